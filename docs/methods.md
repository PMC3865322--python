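# Methods

## Scope and data model

The toolkit analyses aligned plastid barcode libraries: for each locus
(rbcL, matK, optionally the non-coding spacers) one alignment per plant
family, plus a BOLD-style specimen table carrying the taxonomic
hierarchy (family → genus → species → optional infraspecific rank and
epithet), a hybrid flag, the tissue source (silica-dried, herbarium,
existing extract) and the collection year. Sequences and records are
joined on the sample id; orphan sequences and sequence-free records are
reported, never silently dropped, and orphans are excluded from every
analysis. Alignment computation itself (e.g. MUSCLE) is out of scope —
alignments are consumed as input.

### Microinversion reorientation

Short (typically 6 bp) microinversions in non-coding spacers such as
psbA–trnH would otherwise register as multiple substitutions between
sequences that differ only in inversion state. Before any distance or
identity computation, every window of the configured length is compared
with the column-majority consensus (ties broken alphabetically): a row
whose window equals the reverse complement of the consensus window *and*
mismatches the consensus in strictly more than half the positions is
replaced by the consensus-orientation segment. The second clause keeps
windows that equal their own reverse complement (palindromes,
near-palindromes) from being rewritten. Reported positions are 1-based
inclusive; the operation is idempotent.

## Distances

All site comparisons use **pairwise deletion**: a column contributes to a
pair only when both rows carry A, C, G or T. Gaps, N and all other IUPAC
ambiguity codes are treated as missing — a deliberate choice (ambiguity
codes could alternatively be scored as partial matches) that keeps
identity detection conservative; pooled means may shift in the fourth
decimal under other conventions.

* uncorrected p-distance: mismatches / comparable sites;
* K2P: d = −½ ln((1 − 2P − Q)√(1 − 2Q)) with P, Q the transition
  (A↔G, C↔T) and transversion proportions; undefined under saturation.

A pair with fewer than `min_overlap` comparable sites (default **100**)
is *undefined* (NaN), not zero: an undefined distance is excluded from
divergence pools and counts as "not identical" in discrimination. The
default stops ~100 bp fragments — which would be identical to almost
anything — from collapsing taxa. K2P exists only for validation
phenograms; every headline analysis uses uncorrected p.

Divergence pools: for every family matrix, defined distances between
conspecific individuals form the infraspecific pool and between
congeneric heterospecific individuals the congeneric pool; cross-genus
pairs, hybrids and specimens not determined to species are excluded.
Histograms use left-closed right-open bins from zero; counts conserve
the pool size.

## Neighbour joining

Saitou–Nei agglomeration with the Q-criterion. Determinism: ids are
sorted lexicographically before agglomeration and Q-ties break towards
the smallest (i, j) index pair, so shuffled input yields an isomorphic
tree. Negative limb lengths — possible only for non-additive inputs —
are clamped to zero at creation with no length transfer; the trees are
used for visualization and validation, not inference, so the simple
clamp is preferred over redistribution schemes. Undefined distances are
a hard error for the tree builder; the caller resolves them by
iteratively dropping the sample with the most undefined pairs (the drop
list is reported). On additive matrices the leaf-to-leaf path lengths
reproduce the input exactly (observed worst deviation ~4e-15 over 100
random 4–8-taxon matrices).

Validation flags: a sample is "grossly misplaced" when all of its k
(default 3) nearest defined neighbours belong to a different taxon at
the requested level *and* a same-taxon alternative exists in the matrix
(monotypic taxa can never fire).

## Discrimination scoring

"Identical" = zero mismatches over at least `min_overlap` comparable
sites. A taxon is **resolved** when no sequence of any of its
individuals is identical to a sequence of a different taxon at the same
rank. Topological monophyly on the NJ trees is deliberately *not*
required. Hybrids are excluded everywhere; individuals not determined to
the scored rank are excluded at that rank; infraspecific scoring only
considers species with ≥ 2 distinct sampled infraspecific taxa.
Singleton taxa are scored by the same rule.

The best-match route scores individuals against the whole family
alignment with 100 %-similarity rules: an individual passes the genus
rule when it has no 100 % match in another genus, regardless of what its
most similar sequence is; a species fails if any individual matches
another species at 100 %; a singleton species is discriminated iff its
sequence is unique. The similarity engine is exact columnwise identity
over the family alignment rather than a local aligner — the rules only
ever consult 100 % matches, so a local-alignment engine would add
machinery without changing a verdict. Best-match scoring is single-locus
by design; combined-locus scoring uses the haplotype route only.
Concatenation is complete-case (rbcL then matK; individuals lacking
either locus are dropped), which makes resolution monotone: adding a
locus never unresolves a taxon.

Aggregation: per-family and per-genus species-resolution percentages,
with the lists of groups at 100 % and 0 %; the sampling-depth
correlation is the Pearson r between species sampled per genus and
percent resolved, with its two-sided t-test p.

## Recoverability statistics

Recovery = fraction of attempted specimens yielding a sequence for a
locus; families on a locus' exclusion list (e.g. fern families whose
matK primers fail outright) leave both numerator and denominator.
Herbarium specimens are binned into left-closed decade age classes
anchored at 1950 (the earliest herbarium collections sampled); the
newest class may be partial. The two-proportion Z-test uses the pooled
variance and no continuity correction — on the published counts
(2460/2644 vs 2150/2644) this yields Z = 12.7509, truncating to the
printed 12.7; "p = 0" is rendered as p < 1e-15, never literal zero.
Spearman's rho uses average ranks; its two-sided p-value is exact (full
enumeration of the n! rank permutations) for n ≤ 9 — the regime of the
seven-or-eight age classes — and the t-approximation above that.
Statistics are stored signed.

## The synthetic library generator

The generator reproduces identity *patterns*, not genealogies: the
analyses consume who-is-identical-to-whom, so sharing is modelled at the
haplotype-pool level rather than by coalescent simulation.

Construction: one random root sequence per (family, locus); genus bases
mutate from the root, species bases from the genus, within-species
variants from the species base, with per-site substitution
probabilities (defaults 0.02 / 0.005 / 0.002 per level) scaled by a
per-locus rate multiplier (rbcL 1.0, matK 2.6 — matK's higher
variability is what makes it the better discriminator, and with these
defaults the synthetic congeneric divergence ratio emerges at ≈ 2.6).
Substitutions pick sites uniformly with transition:transversion
weighting 2:1; no indels by default (`indel_prob` inserts 6-bp gap runs
to exercise the missing-data policy). A registry enforces that
haplotypes of different species within a family are distinct, so the
*only* sources of cross-taxon identity are the two modelled mechanisms:

* **sharing** — with probability `p_share` (optionally increasing with
  genus size via `clade_share_slope`) a species adopts its genus' pooled
  haplotype at every locus, becoming indistinguishable from congeners
  that did the same;
* **introgression / chloroplast capture** — an event copies a haplotype
  actually carried by a donor individual into a configurable fraction
  (default half) of a recipient congener's individuals at all loci,
  mimicking documented plastid capture between congeneric species.

Dropout: a silica specimen fails a locus with the base probability; a
herbarium specimen fails with sigmoid(logit(base) + herbarium_penalty +
age_coefficient × decades before the anchor year). Defaults (rbcL base
0.07 age-free; matK base 0.15 with 0.25 logit/decade) give ≈ 93 % rbcL
recovery, ≈ 85 % silica matK recovery and an age-driven matK decline in
herbarium material, the contrast the age-class Spearman test detects.
Demographics: 44 % herbarium specimens collected 1950–2010, genus and
species counts truncated-geometric (≈ 2.8 species/genus), 1–27
individuals per species (mean 5), 6 % of species with two infraspecific
taxa (17 % of those haplotype-distinct), 0.5 % hybrids.

Randomness: every entity (family, genus, species, individual, event)
draws from its own generator seeded by (seed, stream-tag, entity
index). Output is bit-for-bit deterministic, and changing one knob
leaves all other entities' draws untouched — which is what makes the
coupled comparisons exact: resolution is provably non-increasing in
`p_share` on a common seed, and the introgression scenario compares
with/without the event on otherwise identical libraries.

### Closed-form companion

In the simple regime (constant independent sharing, no introgression,
no hybrids, no dropout) a species is unresolved iff it and at least one
congener adopted the pool, so a genus of k species contributes
j·1[j ≥ 2] unresolved species with j ~ Binomial(k, p_share).
`expected_unresolved_fraction` enumerates the mean and variance of the
unresolved count and the species count over the genus-size pmf and
combines them with the delta method into a mean and sd for the
library-level fraction. The sd deliberately carries the genus-level
clustering of the draws — a binomial band at the species level would be
too narrow — and the calibration check asks that observed fractions from
replicate libraries fall in the ±1.96 sd band.

## What the synthetic tests do and do not show

The generator reproduces the *mechanisms* (sharing, capture, dropout,
infraspecific structure) but not several features of real libraries:
alignment error, indel-rich spacers (off by default), intragenomic or
sequencing ambiguity, uneven geographic sampling, and taxonomy that is
itself uncertain. Passing the synthetic checks therefore demonstrates
that the scoring, distance and statistical machinery is correct and
calibrated under the stated model — not that any particular real flora
will show the same resolution percentages. The published headline
percentages depend on the actual accession set and are not recomputable
from the text alone; the worked-number checks cover the quantities that
are (recovery percentages, the Z statistic, the divergence ratio).

## Problem sizes and defaults

Desk-scale defaults keep every analysis deterministic and fast: the
reference library uses 10 families (~560 specimens); the oracle
comparison runs 50 libraries of ≤ 200 individuals; NJ exactness uses 100
random 4–8-taxon additive matrices; calibration uses 20 replicate
libraries of ≥ 200 species each. These sizes were chosen so the full
analysis reruns from scratch in well under a minute per stage while
keeping every statistical check adequately powered.

## Known limitations

* Pairwise deletion treats ambiguity codes as missing; libraries rich in
  ambiguous calls lose comparable sites and may push pairs below
  `min_overlap`.
* The microinversion detector keys on the reverse complement of the
  column-majority consensus; an inversion carried by more than half the
  rows would be "the consensus" and the minority orientation would be
  rewritten instead — harmless for distances, but the reported edits
  then name the non-inverted rows.
* NJ tie-breaking is deterministic but arbitrary; degenerate matrices
  (exactly tied Q values) can differ topologically from other
  implementations. Scoring never depends on topology.
* The generator's haplotype-distinctness registry guarantees that
  non-shared species are distinguishable at full length; real congeners
  can be identical for lack of variation, a regime represented here only
  through the sharing mechanism.
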