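"""Neighbour joining, nearest-neighbour queries, and misplacement flags.

The trees built here are diagnostic: discrimination scoring is done from
sequence identity, not topology, so NJ only needs to be deterministic and
exact on additive inputs.  Saitou–Nei agglomeration with the Q-criterion;
ties in Q break towards the smallest (i, j) index pair after sorting
sample ids lexicographically, and negative limb lengths (which arise only
from non-additive inputs) are clamped to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .distances import DistanceMatrix
from .io import Library, UnrootedTree

logger = logging.getLogger(__name__)


def drop_undefined(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Iteratively drop the sample with the most undefined pairs.

    Returns the cleaned matrix and the drop list (possibly empty).  Ties on
    the undefined count break towards the lexicographically largest id, so
    better-annotated early ids survive.
    """
    ids = list(dm.ids)
    d = dm.d.copy()
    comp = dm.comparable.copy()
    dropped: list[str] = []
    while True:
        nan = np.isnan(d)
        np.fill_diagonal(nan, False)
        per = nan.sum(axis=1)
        if per.max(initial=0) == 0:
            break
        worst = max(range(len(ids)), key=lambda i: (per[i], ids[i]))
        dropped.append(ids[worst])
        keep = [i for i in range(len(ids)) if i != worst]
        ids = [ids[i] for i in keep]
        d = d[np.ix_(keep, keep)]
        comp = comp[np.ix_(keep, keep)]
    if dropped:
        logger.info("dropped %d samples with undefined distances: %s",
                    len(dropped), ", ".join(sorted(dropped)))
    return DistanceMatrix(ids=ids, d=d, comparable=comp,
                          model=dm.model), dropped


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Build an unrooted Saitou–Nei neighbour-joining tree.

    On an additive input the leaf-to-leaf path lengths reproduce the input
    distances exactly (up to floating point).  Undefined distances are a
    hard error: resolve them first with :func:`drop_undefined`.
    """
    if dm.n < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(dm.d).any():
        raise ValueError(
            "distance matrix contains undefined pairs; drop or impute them "
            "first (see drop_undefined)")

    order = sorted(range(dm.n), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float)

    tree = UnrootedTree()
    node_of = [tree.add_node(label=s) for s in ids]
    active = list(range(len(ids)))
    dist = {(i, j): d[i, j] for i in range(len(ids))
            for j in range(len(ids)) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    next_idx = len(ids)
    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best: Optional[tuple[float, int, int]] = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * get(i, j) - rowsum[i] - rowsum[j]
                cand = (q, i, j)
                if best is None or cand < best:
                    best = cand
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_idx
        next_idx += 1
        new_node = tree.add_node()
        node_of.append(new_node)
        tree.add_edge(node_of[i], new_node, li)
        tree.add_edge(node_of[j], new_node, lj)
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(k, new), max(k, new))] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new]

    if len(active) == 2:  # the trivial two-sample case
        i, j = active
        tree.add_edge(node_of[i], node_of[j], max(get(i, j), 0.0))
    else:  # final three-way join onto one internal node
        i, j, k = active
        li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
        lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
        lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
        hub = tree.add_node()
        tree.add_edge(node_of[i], hub, max(li, 0.0))
        tree.add_edge(node_of[j], hub, max(lj, 0.0))
        tree.add_edge(node_of[k], hub, max(lk, 0.0))
    return tree


def nearest_neighbors(dm: DistanceMatrix, sample_id: str,
                      k: int = 1) -> list[tuple[str, float]]:
    """The k nearest defined neighbours; ties break lexicographically.

    If fewer than k defined neighbours exist, all are returned and a
    warning is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qi = dm.index(sample_id)
    cand = []
    for j, other in enumerate(dm.ids):
        if j == qi:
            continue
        val = dm.d[qi, j]
        if math.isnan(val):
            continue
        cand.append((float(val), other))
    cand.sort()
    if len(cand) < k:
        logger.warning("sample %s: only %d defined neighbours available "
                       "(k=%d)", sample_id, len(cand), k)
    return [(sid, val) for val, sid in cand[:k]]


@dataclass(frozen=True)
class MisplacementFlag:
    sample_id: str
    level: str
    expected_taxon: str
    neighbors: tuple[tuple[str, str, float], ...]  # (id, taxon, distance)


def flag_misplaced(dm: DistanceMatrix, library: Library, level: str = "family",
                   k: int = 3) -> list[MisplacementFlag]:
    """Flag individuals grossly misplaced relative to their family or genus.

    A sample is flagged when all of its k nearest neighbours belong to a
    different taxon at the requested level AND at least one same-taxon
    alternative exists elsewhere in the matrix (so monotypic taxa never
    fire).  Evidence lists the offending neighbours.
    """
    if level not in ("family", "genus"):
        raise ValueError("level must be 'family' or 'genus'")

    def taxon_of(sid: str) -> Optional[str]:
        rec = library.records.get(sid)
        if rec is None:
            return None
        return rec.family if level == "family" else rec.genus

    taxa = {sid: taxon_of(sid) for sid in dm.ids}
    flags: list[MisplacementFlag] = []
    for sid in dm.ids:
        own = taxa[sid]
        if not own:
            continue
        has_alternative = any(
            other != sid and taxa[other] == own for other in dm.ids)
        if not has_alternative:
            continue
        nbrs = nearest_neighbors(dm, sid, k=k)
        if not nbrs:
            continue
        if all(taxa[nid] and taxa[nid] != own for nid, _ in nbrs):
            flags.append(MisplacementFlag(
                sample_id=sid, level=level, expected_taxon=own,
                neighbors=tuple((nid, taxa[nid] or "?", dist)
                                for nid, dist in nbrs)))
    return flags
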