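"""Taxon-discrimination scoring for barcode reference libraries.

A taxon (genus, species, or infraspecific taxon) is *resolved* by a locus
when none of its individuals carries a sequence identical to a sequence
from a different taxon at the same rank.  "Identical" means zero
mismatches over at least ``min_overlap`` comparable sites under pairwise
deletion — a deliberately conservative identity notion so that short
fragments cannot collapse taxa.  Topological monophyly on the NJ trees is
*not* required; the trees are diagnostic only.

Two scoring routes are provided:

* :func:`haplotype_discrimination` — taxon-centric: pools every individual
  of a taxon and looks for cross-taxon identical sequences.
* :func:`best_match_discrimination` — individual-centric, in the style of
  all-to-all best-match (BLAST-like) library searches scored with 100 %
  similarity rules, including the special rule for singleton species
  (discriminated iff the lone individual's sequence is unique).

With an exact-identity similarity engine the two routes agree
verdict-for-verdict; the test suite asserts this equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .distances import (DEFAULT_MIN_OVERLAP, _pair_count_matrices,
                        encode_matrix, site_pair_counts)
from .io import AlignedMatrix, Library, SpecimenRecord

logger = logging.getLogger(__name__)

LEVELS = ("genus", "species", "infraspecific")


# ---------------------------------------------------------------------------
# identity and concatenation primitives
# ---------------------------------------------------------------------------


def sequences_identical(row_a: str, row_b: str,
                        min_overlap: int = DEFAULT_MIN_OVERLAP) -> bool:
    """True iff zero mismatches over >= min_overlap comparable sites."""
    counts = site_pair_counts(row_a, row_b)
    return counts.mismatches == 0 and counts.comparable_sites >= min_overlap


def concat_loci(matrix_a: AlignedMatrix,
                matrix_b: AlignedMatrix) -> AlignedMatrix:
    """Complete-case concatenation of two loci for one family scope.

    Only individuals sequenced for both loci are retained; rows are joined
    end-to-end in the given order (rbcL then matK in the standard
    two-locus barcode).
    """
    if matrix_a.scope != matrix_b.scope:
        raise ValueError(
            f"scope mismatch: {matrix_a.scope!r} vs {matrix_b.scope!r}")
    shared = [sid for sid in matrix_a.ids if sid in set(matrix_b.ids)]
    if not shared:
        logger.warning("concat_loci(%s, %s): no shared individuals in %s",
                       matrix_a.locus, matrix_b.locus, matrix_a.scope)
    b_row = {sid: s for sid, s in matrix_b.rows}
    a_row = {sid: s for sid, s in matrix_a.rows}
    return AlignedMatrix(
        locus=f"{matrix_a.locus}+{matrix_b.locus}", scope=matrix_a.scope,
        ids=list(shared),
        seqs=[a_row[sid] + b_row[sid] for sid in shared])


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class TaxonEntry:
    taxon: str
    n_individuals: int
    resolved: bool
    shared_with: set[str] = field(default_factory=set)
    rule: str = ""

    @property
    def singleton(self) -> bool:
        return self.n_individuals == 1


@dataclass
class DiscriminationReport:
    level: str
    locus_set: tuple[str, ...]
    method: str
    entries: dict[str, TaxonEntry]

    @property
    def n_taxa(self) -> int:
        return len(self.entries)

    @property
    def n_resolved(self) -> int:
        return sum(e.resolved for e in self.entries.values())

    @property
    def percent_resolved(self) -> float:
        if not self.entries:
            return float("nan")
        return 100.0 * self.n_resolved / self.n_taxa

    def resolved_taxa(self) -> list[str]:
        return sorted(t for t, e in self.entries.items() if e.resolved)

    def unresolved_taxa(self) -> list[str]:
        return sorted(t for t, e in self.entries.items() if not e.resolved)


# ---------------------------------------------------------------------------
# taxon labelling
# ---------------------------------------------------------------------------


def _taxon_label(rec: SpecimenRecord, level: str) -> Optional[str]:
    """The taxon an individual belongs to at a rank, or None if excluded.

    Hybrids are always excluded; individuals not determined to the
    requested rank are excluded from that rank's scoring.
    """
    if rec.is_hybrid:
        return None
    if level == "genus":
        return rec.genus or None
    if level == "species":
        if not rec.species:
            return None
        return rec.binomial
    if level == "infraspecific":
        return rec.infraspecific_label
    raise ValueError(f"unknown level {level!r}")


def _eligible(matrix: AlignedMatrix, library: Library,
              level: str) -> dict[str, str]:
    """Map sample_id -> taxon label for individuals entering the scoring.

    At the infraspecific level only species with >= 2 distinct sampled
    infraspecific taxa enter; rank-indeterminate individuals of those
    species are excluded.
    """
    labels: dict[str, str] = {}
    for sid in matrix.ids:
        rec = library.records.get(sid)
        if rec is None:
            continue
        lab = _taxon_label(rec, level)
        if lab is not None:
            labels[sid] = lab
    if level == "infraspecific":
        per_species: dict[str, set[str]] = {}
        for sid, lab in labels.items():
            rec = library.records[sid]
            per_species.setdefault(rec.binomial, set()).add(lab)
        keep_species = {sp for sp, infras in per_species.items()
                        if len(infras) >= 2}
        labels = {sid: lab for sid, lab in labels.items()
                  if library.records[sid].binomial in keep_species}
    return labels


def _identity_matrix(matrix: AlignedMatrix,
                     min_overlap: int) -> np.ndarray:
    """Boolean all-pairs matrix of the conservative identity relation."""
    codes = encode_matrix(matrix)
    comparable, mismatches, _ = _pair_count_matrices(codes)
    return (mismatches == 0) & (comparable >= min_overlap)


# ---------------------------------------------------------------------------
# scoring routes
# ---------------------------------------------------------------------------


def haplotype_discrimination(
        matrix: AlignedMatrix, library: Library, level: str = "species",
        min_overlap: int = DEFAULT_MIN_OVERLAP) -> DiscriminationReport:
    """Taxon-centric scoring: resolved iff no cross-taxon identical sequence.

    Singleton taxa are scored by the same rule.  ``shared_with`` records,
    symmetrically, the other taxa with which identical sequences occur.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    labels = _eligible(matrix, library, level)
    ids = [sid for sid in matrix.ids if sid in labels]
    sub = AlignedMatrix(locus=matrix.locus, scope=matrix.scope,
                        ids=ids, seqs=[matrix.row(s) for s in ids])
    entries: dict[str, TaxonEntry] = {}
    for sid in ids:
        lab = labels[sid]
        e = entries.setdefault(lab, TaxonEntry(lab, 0, resolved=True))
        e.n_individuals += 1
    if ids:
        ident = _identity_matrix(sub, min_overlap)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                li, lj = labels[ids[i]], labels[ids[j]]
                if li != lj and ident[i, j]:
                    entries[li].shared_with.add(lj)
                    entries[lj].shared_with.add(li)
    for e in entries.values():
        e.resolved = not e.shared_with
        e.rule = "no-shared-haplotype" if e.resolved else "shared-haplotype"
    return DiscriminationReport(level=level, locus_set=(matrix.locus,),
                                method="haplotype", entries=entries)


def best_match_discrimination(
        matrix: AlignedMatrix, library: Library, level: str = "species",
        min_overlap: int = DEFAULT_MIN_OVERLAP) -> DiscriminationReport:
    """Individual-centric all-to-all best-match scoring, one locus at a time.

    Genus rule: an individual passes when it has no 100 %-similarity match
    with an individual of another genus, regardless of which taxon its
    closest match belongs to; a genus is discriminated when every
    individual of its sampled species passes.  Species rules: a species
    fails if any individual has a barcode identical to one from another
    species; a singleton species is discriminated iff its individual's
    sequence is unique in the library.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    labels = _eligible(matrix, library, level)
    ids = [sid for sid in matrix.ids if sid in labels]
    sub = AlignedMatrix(locus=matrix.locus, scope=matrix.scope,
                        ids=ids, seqs=[matrix.row(s) for s in ids])
    entries: dict[str, TaxonEntry] = {}
    for sid in ids:
        lab = labels[sid]
        e = entries.setdefault(lab, TaxonEntry(lab, 0, resolved=True))
        e.n_individuals += 1
    if ids:
        ident = _identity_matrix(sub, min_overlap)
        np.fill_diagonal(ident, False)
        for i, sid in enumerate(ids):
            lab = labels[sid]
            matches = np.flatnonzero(ident[i])
            cross = [ids[j] for j in matches if labels[ids[j]] != lab]
            if cross:
                e = entries[lab]
                e.resolved = False
                e.shared_with.update(labels[c] for c in cross)
                for c in cross:  # symmetric bookkeeping
                    entries[labels[c]].shared_with.add(lab)
                    entries[labels[c]].resolved = False
    for e in entries.values():
        if e.singleton:
            e.rule = ("singleton-unique-sequence" if e.resolved
                      else "singleton-matched-other-taxon")
        else:
            e.rule = ("no-100%-match-other-taxon" if e.resolved
                      else "100%-match-other-taxon")
    return DiscriminationReport(level=level, locus_set=(matrix.locus,),
                                method="best_match", entries=entries)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class ResolutionSummary:
    grouping: str  # "family" | "genus"
    rows: list[tuple[str, int, int, float]]  # group, n_sampled, n_resolved, %

    @property
    def fully_resolved(self) -> list[str]:
        return [g for g, n, r, _ in self.rows if n > 0 and r == n]

    @property
    def fully_unresolved(self) -> list[str]:
        return [g for g, n, r, _ in self.rows if n > 0 and r == 0]

    def as_dict(self) -> dict[str, tuple[int, int, float]]:
        return {g: (n, r, pct) for g, n, r, pct in self.rows}


def resolution_summary(report: DiscriminationReport, library: Library,
                       grouping: str = "family") -> ResolutionSummary:
    """Per-family or per-genus species-resolution percentages.

    Expects a species-level report; each species is attributed to its
    genus/family via the specimen records.
    """
    if grouping not in ("family", "genus"):
        raise ValueError("grouping must be 'family' or 'genus'")
    if report.level != "species":
        raise ValueError("resolution_summary expects a species-level report")
    group_of_species: dict[str, str] = {}
    for rec in library.records.values():
        if rec.is_hybrid or not rec.species:
            continue
        group_of_species[rec.binomial] = (
            rec.family if grouping == "family" else rec.genus)
    tall: dict[str, list[int]] = {}
    for taxon, entry in report.entries.items():
        group = group_of_species.get(taxon)
        if group is None:
            continue
        cell = tall.setdefault(group, [0, 0])
        cell[0] += 1
        cell[1] += int(entry.resolved)
    rows = [(g, n, r, 100.0 * r / n)
            for g, (n, r) in sorted(tall.items())]
    return ResolutionSummary(grouping=grouping, rows=rows)


def merge_reports(reports: list[DiscriminationReport]) -> DiscriminationReport:
    """Combine per-family reports for one locus/level into one report."""
    if not reports:
        raise ValueError("no reports to merge")
    level = reports[0].level
    method = reports[0].method
    locus_set = reports[0].locus_set
    entries: dict[str, TaxonEntry] = {}
    for rep in reports:
        if rep.level != level:
            raise ValueError("cannot merge reports at different levels")
        for taxon, e in rep.entries.items():
            if taxon in entries:
                prev = entries[taxon]
                prev.n_individuals += e.n_individuals
                prev.shared_with |= e.shared_with
                prev.resolved = prev.resolved and e.resolved
            else:
                entries[taxon] = TaxonEntry(
                    taxon, e.n_individuals, e.resolved,
                    set(e.shared_with), e.rule)
    return DiscriminationReport(level=level, locus_set=locus_set,
                                method=method, entries=entries)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    flagged: bool = False
    note: str = ""


def sampling_resolution_correlation(
        summary: ResolutionSummary) -> CorrelationResult:
    """Pearson correlation of species sampled per genus vs % resolved.

    Requires a genus-level summary with >= 3 genera; zero variance in
    either variable is flagged rather than raising.
    """
    if summary.grouping != "genus":
        raise ValueError("expects a genus-level summary")
    x = np.array([n for _, n, _, _ in summary.rows], dtype=float)
    y = np.array([pct for _, _, _, pct in summary.rows], dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 genera")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=float("nan"), p_value=float("nan"),
                                 n=n, flagged=True,
                                 note="zero variance in one variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=n)
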