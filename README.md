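# barcodekit

Analysis toolkit for plastid DNA-barcode reference libraries (rbcL,
matK, and the supplementary spacers psbA–trnH, psbK–psbI, atpF–atpH),
built for floristic barcoding campaigns of the kind run for Arctic
vascular plants: thousands of vouchered specimens, per-family alignments
per locus, and the recurring question of *which taxa the barcodes can
actually tell apart*.

## What it computes

**Distances.** Uncorrected *p*-distance (mismatches / comparable sites)
and the Kimura two-parameter correction
d = −½ ln((1 − 2P − Q)·√(1 − 2Q)), both under pairwise deletion: a
column counts for a pair only when both rows carry an unambiguous base.
Pairs with fewer than `min_overlap` (default 100) comparable sites are
*undefined*, never zero, so short fragments cannot fake identity.

**Trees.** Deterministic Saitou–Nei neighbour joining (lexicographic
tie-breaks, negative limbs clamped to zero), exact on additive matrices,
written as Newick. Trees are diagnostic — scoring does not depend on
topology — and a misplacement scan flags individuals whose k nearest
neighbours all belong to a different family/genus.

**Discrimination.** A taxon (genus, species, infraspecific taxon) is
*resolved* by a locus when none of its individuals has a sequence
identical to one from another taxon at that rank, where "identical"
means zero mismatches over ≥ `min_overlap` comparable sites. Two routes
are scored — taxon-centric haplotype sharing and individual-centric
all-to-all best match with 100 %-similarity rules (including the
singleton rule: a one-individual species is discriminated iff its
sequence is unique) — and they agree verdict-for-verdict under exact
identity. Loci can be concatenated complete-case (rbcL then matK,
keeping only individuals sequenced for both). Per-family/per-genus
resolution percentages and the sampling-depth-vs-resolution Pearson
correlation round out the reporting.

**Recoverability.** Recovery tables by locus, family, source and decade
age class; pooled two-proportion Z-tests; Spearman rank correlation with
exact permutation p-values for n ≤ 9.

**Synthetic libraries.** A ground-truth-instrumented generator emulating
the structure these analyses confront: multi-family taxonomy, per-species
haplotype pools, haplotype *sharing* among congeners (a species adopts
its genus' pooled haplotype with probability `p_share`, optionally
increasing with genus size), *chloroplast capture* (a donor species'
haplotype overwriting recipient individuals), infraspecific taxa,
hybrids, and source/age-dependent locus dropout. Every draw is recorded,
so scoring can be checked against the generator's own bookkeeping.

## Worked example

```sh
python analysis/01_simulate_library.py   # writes scratch/library/
python analysis/04_discrimination.py
```

prints, for the default desk-scale library (seed 0):

```
specimens: 557  sequences: 957
families: 10  genera: 43  species: 108

rbcL      genus            43/43   (100.0%)
rbcL      species          90/106  ( 84.9%)
matK      species          87/101  ( 86.1%)
combined  species          85/99   ( 85.9%)

clade-structured sharing: Pearson r = -0.6808 (n = 61 genera, p = 1.57e-09)
```

Read: every genus is distinguished, but haplotype sharing leaves ~15 %
of species without a diagnostic barcode, and (with sharing that grows
with genus size) the more species a genus has, the lower the fraction
resolved — a significant negative correlation, as observed in real
Arctic libraries. The other drivers follow the same pattern:
`02_recovery_stats.py` (recovery percentages, Z = 12.75 on the published
counts, the matK-but-not-rbcL age effect), `03_divergence.py`
(barcode-gap pools; the synthetic matK/rbcL congeneric divergence ratio
comes out at 2.64 vs the published 2.6), `05_introgression.py` (a
planted capture event unresolves exactly donor and recipient), and
`06_trees.py` (per-family NJ phenograms plus the misplacement scan).

The command-line entry point `barcodekit` exposes the same stages
(`load`, `distances`, `tree`, `discriminate`, `recovery`, `simulate`)
for use on FASTA + metadata files.

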