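"""Sequence-recoverability bookkeeping and the study's inferential tests.

Recoverability is the fraction of sampled specimens yielding a usable
sequence for a locus.  Herbarium material degrades with age, and longer
amplicons (matK, ca. 800 bp) suffer more than short ones (rbcL, 552 bp);
the tests here — pooled two-proportion Z, decade age-class binning with a
Spearman rank correlation, and Pearson r — quantify those contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Library, SpecimenRecord

GROUPINGS = ("locus", "family", "source", "age_class", "locus_by_source")

#: Earliest sampled herbarium collection year; decade bins anchor here.
DEFAULT_ANCHOR_YEAR = 1950
DEFAULT_CLASS_WIDTH = 10


@dataclass
class StatResult:
    """A named test statistic with its two-sided p-value.

    ``statistic`` is stored signed; displays may show the magnitude.
    ``flagged`` marks undefined results (zero variance, degenerate pooled
    proportion) — the statistic is NaN in that case, never a fake zero.
    """

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    flagged: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return (not self.flagged) and self.p_value < 0.05


# ---------------------------------------------------------------------------
# recovery tables
# ---------------------------------------------------------------------------


def age_class_bins(records: Iterable[SpecimenRecord],
                   class_width_years: int = DEFAULT_CLASS_WIDTH,
                   anchor_year: int = DEFAULT_ANCHOR_YEAR,
                   ) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Assign herbarium specimens to left-closed decade age classes.

    Returns ``(assignment, excluded)`` where the assignment maps sample_id
    to a ``(start, end_exclusive)`` class and ``excluded`` lists records
    lacking a collection year.  The newest class may be partial (e.g. a
    single-year class for the current decade).  Records collected before
    the anchor year are a hard error — choose an earlier anchor instead.
    """
    if class_width_years < 1:
        raise ValueError("class_width_years must be >= 1")
    assignment: dict[str, tuple[int, int]] = {}
    excluded: list[str] = []
    for rec in records:
        if rec.collection_year is None:
            excluded.append(rec.sample_id)
            continue
        if rec.collection_year < anchor_year:
            raise ValueError(
                f"{rec.sample_id}: year {rec.collection_year} precedes "
                f"anchor {anchor_year}")
        start = anchor_year + class_width_years * (
            (rec.collection_year - anchor_year) // class_width_years)
        assignment[rec.sample_id] = (start, start + class_width_years)
    return assignment, excluded


def recovery_table(library: Library, grouping: str = "locus",
                   exclude_families: Mapping[str, Sequence[str]] | None = None,
                   loci: Optional[Sequence[str]] = None,
                   class_width_years: int = DEFAULT_CLASS_WIDTH,
                   anchor_year: int = DEFAULT_ANCHOR_YEAR) -> pd.DataFrame:
    """Per-group recovery counts and percentages.

    ``exclude_families`` maps a locus to families removed from both its
    numerator and denominator (e.g. fern and horsetail families whose matK
    primers fail outright).  A specimen counts as attempted for every
    locus; it counts as recovered when a sequence for that locus is
    linked.  Groupings: per ``locus``, per ``family``/``source``/
    ``age_class`` (each crossed with locus), ``locus_by_source``, and the
    pooled ``source`` view.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; "
                         f"expected one of {GROUPINGS}")
    exclude_families = exclude_families or {}
    loci = list(loci) if loci is not None else library.loci
    if not loci:
        raise ValueError("no loci present in the library")

    age_assignment: dict[str, tuple[int, int]] = {}
    if grouping == "age_class":
        herb = [r for r in library.records.values()
                if r.source == "herbarium"]
        age_assignment, _ = age_class_bins(
            herb, class_width_years, anchor_year)

    rows: dict[tuple, list[int]] = {}
    for sid, rec in sorted(library.records.items()):
        for locus in loci:
            if rec.family in exclude_families.get(locus, ()):
                continue
            recovered = locus in library.sequences.get(sid, {})
            if grouping == "locus":
                key = (locus,)
            elif grouping == "family":
                key = (locus, rec.family)
            elif grouping == "locus_by_source":
                key = (locus, rec.source)
            elif grouping == "source":
                key = (rec.source,)
            else:  # age_class
                if sid not in age_assignment:
                    continue
                start, end = age_assignment[sid]
                key = (locus, f"[{start},{end})")
            cell = rows.setdefault(key, [0, 0])
            cell[0] += 1
            cell[1] += int(recovered)
    out = []
    for key in sorted(rows):
        attempted, recovered = rows[key]
        out.append({
            "group": "|".join(str(k) for k in key),
            "n_attempted": attempted,
            "n_recovered": recovered,
            "percent": 100.0 * recovered / attempted,
        })
    return pd.DataFrame(out,
                        columns=["group", "n_attempted", "n_recovered",
                                 "percent"])


# ---------------------------------------------------------------------------
# inferential statistics
# ---------------------------------------------------------------------------


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> StatResult:
    """Pooled-variance two-sided two-proportion Z-test.

    Z = (p1 - p2) / sqrt(pbar (1-pbar) (1/n1 + 1/n2)) with the pooled
    pbar = (x1+x2)/(n1+n2).  No continuity correction.  A degenerate
    pooled proportion (0 or 1) is flagged, not raised.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n with n >= 1 on both sides")
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return StatResult(math.nan, math.nan, "two_proportion_z_pooled",
                          (n1, n2), flagged=True)
    z = ((x1 / n1 - x2 / n2)
         / math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2)))
    p = 2.0 * stats.norm.sf(abs(z))
    return StatResult(statistic=z, p_value=float(p),
                      method="two_proportion_z_pooled", n=(n1, n2))


#: Sample size at or below which the Spearman p-value is exact.
SPEARMAN_EXACT_MAX_N = 9


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with ties averaged.

    The two-sided p-value is exact (full permutation enumeration) for
    n <= 9 and the usual t-approximation for larger n.  Zero rank
    variance is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return StatResult(math.nan, math.nan, "spearman", (n,), flagged=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(permutations(ry)))
        zx = (rx - rx.mean()) / rx.std()
        zp = (perms - perms.mean(axis=1, keepdims=True)) \
            / perms.std(axis=1, keepdims=True)
        rho_all = zp @ zx / n
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        method = "spearman_exact"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        method = "spearman_t"
    return StatResult(statistic=rho, p_value=min(p, 1.0), method=method,
                      n=(n,))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Sample Pearson correlation with two-sided t-test p; reports r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        return StatResult(math.nan, math.nan, "pearson", (n,), flagged=True)
    r, p = stats.pearsonr(x, y)
    return StatResult(statistic=float(r), p_value=float(p), method="pearson",
                      n=(n,), extra={"r_squared": float(r) ** 2})
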