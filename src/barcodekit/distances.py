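"""Pairwise genetic distances and divergence summaries.

Two models are provided: uncorrected *p*-distance (the workhorse of every
headline analysis here) and the Kimura two-parameter (K2P) correction,
kept only for validation phenograms.  All site comparisons use pairwise
deletion: a column contributes to a pair only when both rows carry an
unambiguous base (A/C/G/T); gaps, N and every other IUPAC ambiguity code
are treated as missing.  Pairs whose comparable-site count falls below
``min_overlap`` are *undefined* (NaN), never zero — a short fragment must
not masquerade as an identical sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .io import AlignedMatrix, Library

#: Default minimum number of comparable sites for a defined distance.
DEFAULT_MIN_OVERLAP = 100

# Base encoding: A=0, C=1, G=2, T=3; everything else (gap, N, ambiguity)
# is MISSING.  With this code, two differing bases are a transition iff
# their codes share parity (A<->G both even, C<->T both odd).
_MISSING = 255
_CODE = np.full(256, _MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(residues: str) -> np.ndarray:
    """Encode residues to uint8 codes (A=0,C=1,G=2,T=3, missing=255)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def encode_matrix(matrix: AlignedMatrix) -> np.ndarray:
    """(n_rows, n_columns) uint8 code array for an alignment."""
    if matrix.n_rows == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    return np.vstack([encode(s) for s in matrix.seqs])


@dataclass(frozen=True)
class SitePairCounts:
    """Per-pair site bookkeeping under pairwise deletion."""

    comparable_sites: int
    mismatches: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.mismatches != self.transitions + self.transversions:
            raise ValueError("mismatches must equal transitions+transversions")
        if not 0 <= self.mismatches <= self.comparable_sites:
            raise ValueError("mismatches outside [0, comparable_sites]")

    @property
    def p(self) -> float:
        """Mismatch proportion (undefined -> NaN)."""
        if self.comparable_sites == 0:
            return math.nan
        return self.mismatches / self.comparable_sites


def site_pair_counts(row_a: str, row_b: str) -> SitePairCounts:
    """Count comparable sites, mismatches, transitions and transversions.

    Columns where either row carries a gap, an N or any ambiguity code are
    excluded (pairwise deletion).  Transitions are A<->G and C<->T;
    transversions are all other base mismatches.
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"rows differ in length ({len(row_a)} vs {len(row_b)})")
    a, b = encode(row_a), encode(row_b)
    both = (a != _MISSING) & (b != _MISSING)
    diff = both & (a != b)
    ts = diff & ((a & 1) == (b & 1))
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return SitePairCounts(comparable_sites=int(both.sum()),
                          mismatches=n_diff, transitions=n_ts,
                          transversions=n_diff - n_ts)


def p_distance(counts: SitePairCounts) -> float:
    """Uncorrected p-distance: mismatches / comparable sites (NaN if none)."""
    return counts.p


def k2p_distance(counts: SitePairCounts) -> float:
    """Kimura two-parameter distance.

    d = -(1/2) ln((1-2P-Q) sqrt(1-2Q)) with P, Q the transition and
    transversion proportions.  Returns NaN when the correction is
    undefined (saturation: 1-2P-Q <= 0 or 1-2Q <= 0, or zero overlap).
    """
    if counts.comparable_sites == 0:
        return math.nan
    p = counts.transitions / counts.comparable_sites
    q = counts.transversions / counts.comparable_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with comparable-site counts.

    Undefined distances (insufficient overlap or an inapplicable K2P
    correction) are NaN in ``d``; the diagonal is zero by construction.
    """

    ids: list[str]
    d: np.ndarray
    comparable: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.comparable.shape != (n, n):
            raise ValueError("matrix shapes do not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        nan = np.isnan(self.d)
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if nan[i, j]:
                    out.append((self.ids[i], self.ids[j]))
        return out

    def subset(self, ids: Iterable[str]) -> "DistanceMatrix":
        keep = [self.index(s) for s in ids]
        return DistanceMatrix(ids=[self.ids[i] for i in keep],
                              d=self.d[np.ix_(keep, keep)].copy(),
                              comparable=self.comparable[np.ix_(keep, keep)].copy(),
                              model=self.model)


def _pair_count_matrices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]:
    """All-pairs (comparable, mismatches, transitions) via indicator matmuls."""
    valid = (codes != _MISSING)
    ind = [(codes == base) for base in range(4)]
    f = np.float64
    comparable = valid.astype(f) @ valid.astype(f).T
    matches = sum((m.astype(f) @ m.astype(f).T for m in ind))
    purine = (ind[0] | ind[2]).astype(f)
    pyrim = (ind[1] | ind[3]).astype(f)
    same_class = purine @ purine.T + pyrim @ pyrim.T
    mismatches = comparable - matches
    transitions = same_class - matches
    return (np.rint(comparable).astype(np.int64),
            np.rint(mismatches).astype(np.int64),
            np.rint(transitions).astype(np.int64))


def distance_matrix(matrix: AlignedMatrix, model: str = "p",
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All pairwise distances for one alignment.

    Pairs with fewer than ``min_overlap`` comparable sites are undefined
    (NaN).  The computation is vectorised over indicator matrices; an
    independent per-pair recount is exercised by the test suite.
    """
    if matrix.n_rows < 2:
        raise ValueError("need at least 2 rows")
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown model {model!r}")
    codes = encode_matrix(matrix)
    comparable, mismatches, transitions = _pair_count_matrices(codes)
    n = matrix.n_rows
    with np.errstate(invalid="ignore", divide="ignore"):
        if model == "p":
            d = mismatches / comparable
        else:
            p = transitions / comparable
            q = (mismatches - transitions) / comparable
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            d = np.where((w1 > 0) & (w2 > 0),
                         -0.5 * np.log(np.abs(w1) * np.sqrt(np.abs(w2))),
                         np.nan)
    d = np.asarray(d, dtype=float)
    d[comparable < min_overlap] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(matrix.ids), d=d,
                          comparable=comparable, model=model)


# ---------------------------------------------------------------------------
# divergence summaries (the barcode-gap ingredients)
# ---------------------------------------------------------------------------


@dataclass
class PairwiseSummary:
    """Pooled pairwise distances for one comparison category."""

    category: str  # "infraspecific" | "congeneric_interspecific"
    distances: np.ndarray
    mean: Optional[float]
    sd: Optional[float]

    @property
    def n_comparisons(self) -> int:
        return int(self.distances.size)


def _summary(category: str, pool: list[float]) -> PairwiseSummary:
    arr = np.asarray(pool, dtype=float)
    if arr.size == 0:
        return PairwiseSummary(category, arr, mean=None, sd=None)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PairwiseSummary(category, arr, mean=float(arr.mean()), sd=sd)


def pairwise_summary(
        dms: Mapping[str, DistanceMatrix],
        library: Library) -> tuple[PairwiseSummary, PairwiseSummary]:
    """Pool within-species and within-genus-between-species distances.

    ``dms`` maps a scope (family) to its distance matrix.  Every defined
    distance between conspecific individuals joins the infraspecific pool;
    every defined distance between congeneric heterospecific individuals
    joins the congeneric pool.  Cross-genus pairs, hybrids, and specimens
    not determined to species are excluded.
    """
    intra: list[float] = []
    inter: list[float] = []
    for dm in dms.values():
        recs = []
        for sid in dm.ids:
            r = library.records.get(sid)
            recs.append(r)
        for i in range(dm.n):
            ri = recs[i]
            if ri is None or ri.is_hybrid or not ri.species:
                continue
            for j in range(i + 1, dm.n):
                rj = recs[j]
                if rj is None or rj.is_hybrid or not rj.species:
                    continue
                if ri.genus != rj.genus:
                    continue
                val = dm.d[i, j]
                if math.isnan(val):
                    continue
                if ri.species == rj.species:
                    intra.append(float(val))
                else:
                    inter.append(float(val))
    return (_summary("infraspecific", intra),
            _summary("congeneric_interspecific", inter))


def divergence_histogram(summary: PairwiseSummary,
                         bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed right-open bins from zero; counts conserve n_comparisons.

    Returns (left_edges, counts).  An empty pool yields one empty bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = summary.distances
    if vals.size == 0:
        return np.array([0.0]), np.array([0])
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # floor() keeps bin membership left-closed right-open
    idx = np.floor(vals / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return edges[:-1], counts
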