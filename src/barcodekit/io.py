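"""Data model and I/O for plastid barcode libraries.

Sequences live in per-locus, per-family alignments (FASTA); specimen
metadata comes from a BOLD-style tab-separated voucher table; trees are
written as Newick.  This module also owns the one alignment-level
preprocessing step the analyses need: reorienting short microinversions
in non-coding spacers so that every sequence carries the same inversion
state before distances are computed.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical plastid barcode loci handled by the toolkit.
LOCI = ("rbcL", "matK", "psbA-trnH", "psbK-psbI", "atpF-atpH")

SOURCES = ("silica", "herbarium", "extract")

#: Legal residue characters: the four bases, IUPAC ambiguity codes, gap.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

MIN_YEAR = 1800


def reverse_complement(segment: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes and gaps."""
    return segment.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenRecord:
    """One vouchered individual with its taxonomic hierarchy.

    ``species`` is the specific epithet (the binomial is ``genus`` +
    ``species``); ``infraspecific`` is a ``(rank, epithet)`` pair with rank
    in {"subsp.", "var."} when the specimen is determined below species
    level.  ``source`` records the tissue provenance used by the
    recoverability analyses.
    """

    sample_id: str
    family: str
    genus: str = ""
    species: str = ""
    infraspecific: Optional[tuple[str, str]] = None
    is_hybrid: bool = False
    source: str = "silica"
    collection_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.species and not self.genus:
            raise ValueError(
                f"{self.sample_id}: species given without genus")
        if self.genus and not self.family:
            raise ValueError(
                f"{self.sample_id}: genus given without family")
        if self.source not in SOURCES:
            raise ValueError(
                f"{self.sample_id}: unknown source {self.source!r}")
        if self.collection_year is not None:
            this_year = datetime.date.today().year
            if not (MIN_YEAR <= self.collection_year <= this_year):
                raise ValueError(
                    f"{self.sample_id}: collection_year "
                    f"{self.collection_year} outside [{MIN_YEAR}, {this_year}]")

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}" if self.species else self.genus

    @property
    def infraspecific_label(self) -> Optional[str]:
        if self.infraspecific is None:
            return None
        rank, epithet = self.infraspecific
        return f"{self.binomial} {rank} {epithet}"


@dataclass(frozen=True)
class BarcodeSequence:
    """A single barcode sequence tied to a specimen and a locus."""

    sample_id: str
    locus: str
    residues: str
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if not self.residues:
            raise ValueError(f"{self.sample_id}: empty sequence")
        residues = self.residues.upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{self.sample_id}: illegal character {ch!r} "
                    f"at position {pos}")
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedMatrix:
    """Equal-length sequence rows for one locus within one family scope."""

    locus: str
    scope: str
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample ids in alignment")
        if self.seqs:
            ncol = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != ncol:
                    raise ValueError(
                        f"row {sid} has length {len(s)}, expected {ncol}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.seqs))

    def row(self, sample_id: str) -> str:
        return self.seqs[self.ids.index(sample_id)]

    @classmethod
    def from_sequences(cls, sequences: Iterable[BarcodeSequence],
                       scope: str) -> "AlignedMatrix":
        seqs = list(sequences)
        if not seqs:
            raise ValueError("cannot build an alignment from zero sequences")
        locus = seqs[0].locus
        for s in seqs:
            if s.locus != locus:
                raise ValueError("mixed loci in one alignment")
        return cls(locus=locus, scope=scope,
                   ids=[s.sample_id for s in seqs],
                   seqs=[s.residues for s in seqs])


class UnrootedTree:
    """Unrooted tree with labelled leaves and non-negative branch lengths.

    Stored as an adjacency map; internal nodes are unlabelled integers.
    """

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {}
        self._label: dict[int, str] = {}
        self._next = 0

    def add_node(self, label: Optional[str] = None) -> int:
        node = self._next
        self._next += 1
        self._adj[node] = {}
        if label is not None:
            if label in self._label.values():
                raise ValueError(f"duplicate leaf label {label!r}")
            self._label[node] = label
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise ValueError("branch lengths must be non-negative")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    # -- queries ------------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._label.values())

    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def _leaf_nodes(self) -> dict[str, int]:
        return {lab: node for node, lab in self._label.items()}

    def path_length_matrix(self) -> tuple[list[str], "pd.DataFrame"]:
        """Leaf-to-leaf path lengths (substitutions/site) as a DataFrame."""
        import numpy as np

        labels = self.leaf_labels
        by_label = self._leaf_nodes()
        n = len(labels)
        out = np.zeros((n, n))
        for i, lab in enumerate(labels):
            dist = {by_label[lab]: 0.0}
            stack = [by_label[lab]]
            while stack:
                u = stack.pop()
                for v, w in self._adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, other in enumerate(labels):
                out[i, j] = dist[by_label[other]]
        return labels, pd.DataFrame(out, index=labels, columns=labels)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each given as the side not containing
        the lexicographically smallest leaf."""
        labels = self.leaf_labels
        if len(labels) < 4:
            return set()
        anchor = labels[0]
        result: set[frozenset[str]] = set()
        for u in self._adj:
            for v in self._adj[u]:
                if u > v:
                    continue
                side = self._component_leaves(u, blocked=v)
                if anchor in side:
                    side = frozenset(set(labels) - side)
                else:
                    side = frozenset(side)
                if 2 <= len(side) <= len(labels) - 2:
                    result.add(side)
        return result

    def _component_leaves(self, start: int, blocked: int) -> set[str]:
        seen = {start}
        stack = [start]
        leaves = set()
        while stack:
            u = stack.pop()
            if u in self._label:
                leaves.add(self._label[u])
            for v in self._adj[u]:
                if v != blocked and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return leaves

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        if len(self._label) < 2:
            raise ValueError("need at least 2 leaves to write Newick")
        # root at an internal node when one exists, else at the first leaf
        internal = [n for n in self._adj if n not in self._label]
        if internal:
            root = max(internal, key=lambda n: len(self._adj[n]))
        else:  # two-leaf tree: split the single edge evenly
            a, b = sorted(self._label, key=self._label.get)
            half = self._adj[a][b] / 2.0
            return f"({self._label[a]}:{half!r},{self._label[b]}:{half!r});"

        def render(node: int, parent: int) -> str:
            children = [v for v in sorted(self._adj[node]) if v != parent]
            if not children:
                return self._label[node]
            inner = ",".join(
                f"{render(v, node)}:{self._adj[node][v]!r}" for v in children)
            return f"({inner})"

        return render(root, parent=-1) + ";"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, locus: str,
               aligned: bool = False) -> list[BarcodeSequence]:
    """Read a (possibly empty) FASTA file into BarcodeSequence records.

    The first whitespace-delimited token of each header is the sample id.
    Residues are upper-cased; duplicate ids and illegal characters are
    hard errors.
    """
    out: list[BarcodeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r} in {path}")
        seen.add(sid)
        out.append(BarcodeSequence(sample_id=sid, locus=locus,
                                   residues=str(rec.seq), aligned=aligned))
    return out


def write_fasta(sequences: Sequence[BarcodeSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.sample_id, description="")
               for s in sequences]
    SeqIO.write(records, str(path), "fasta")


_REQUIRED_COLUMNS = ("sample_id", "family", "genus", "species")
_TRUTHY = {"1", "true", "yes", "y", "t"}


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a BOLD-style tab-separated specimen table.

    Required columns: sample_id, family, genus, species.  Optional:
    infraspecific_rank, infraspecific_epithet, is_hybrid, source,
    collection_year.  An unparseable year is logged and dropped; a missing
    required column is a hard error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata table missing required columns: {missing}")
    records: list[SpecimenRecord] = []
    for _, row in table.iterrows():
        year: Optional[int] = None
        raw_year = row.get("collection_year", "").strip()
        if raw_year:
            try:
                year = int(raw_year)
            except ValueError:
                logger.warning(
                    "sample %s: unparseable collection_year %r; "
                    "treating as absent", row["sample_id"], raw_year)
        infra = None
        rank = row.get("infraspecific_rank", "").strip()
        epithet = row.get("infraspecific_epithet", "").strip()
        if rank and epithet:
            infra = (rank, epithet)
        records.append(SpecimenRecord(
            sample_id=row["sample_id"].strip(),
            family=row["family"].strip(),
            genus=row["genus"].strip(),
            species=row["species"].strip(),
            infraspecific=infra,
            is_hybrid=row.get("is_hybrid", "").strip().lower() in _TRUTHY,
            source=row.get("source", "").strip() or "silica",
            collection_year=year,
        ))
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rank, epithet = r.infraspecific if r.infraspecific else ("", "")
        rows.append({
            "sample_id": r.sample_id, "family": r.family, "genus": r.genus,
            "species": r.species, "infraspecific_rank": rank,
            "infraspecific_epithet": epithet,
            "is_hybrid": "1" if r.is_hybrid else "0",
            "source": r.source,
            "collection_year": "" if r.collection_year is None
            else str(r.collection_year),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_newick(tree: UnrootedTree, path: str | Path) -> None:
    """Write the tree as standard Newick with full-precision branch lengths."""
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# the linked library
# ---------------------------------------------------------------------------


@dataclass
class Library:
    """Specimen records joined to their sequences.

    ``orphan_sequence_ids`` are sequences with no metadata record (they are
    excluded from all analyses); ``records_without_sequences`` are specimens
    for which no locus was recovered.  Neither condition is fatal.
    """

    records: dict[str, SpecimenRecord]
    sequences: dict[str, dict[str, BarcodeSequence]]  # sample -> locus -> seq
    orphan_sequence_ids: set[str] = field(default_factory=set)
    records_without_sequences: set[str] = field(default_factory=set)

    @property
    def loci(self) -> list[str]:
        found = {loc for per in self.sequences.values() for loc in per}
        return [loc for loc in LOCI if loc in found]

    @property
    def families(self) -> list[str]:
        return sorted({r.family for r in self.records.values()})

    def sequences_for(self, locus: str,
                      family: Optional[str] = None) -> list[BarcodeSequence]:
        out = []
        for sid in sorted(self.sequences):
            if family is not None and self.records[sid].family != family:
                continue
            if locus in self.sequences[sid]:
                out.append(self.sequences[sid][locus])
        return out

    def matrix(self, locus: str, family: str) -> Optional[AlignedMatrix]:
        seqs = self.sequences_for(locus, family)
        if not seqs:
            return None
        return AlignedMatrix.from_sequences(seqs, scope=family)

    def matrices(self, locus: str) -> dict[str, AlignedMatrix]:
        out = {}
        for fam in self.families:
            m = self.matrix(locus, fam)
            if m is not None:
                out[fam] = m
        return out


def link(records: Iterable[SpecimenRecord],
         sequences: Iterable[BarcodeSequence]) -> Library:
    """Join sequences to specimen records; nothing is dropped silently.

    Counts are conserved: every input sequence is either linked or reported
    as an orphan; every record either has sequences or is reported as
    sequence-free.
    """
    rec_by_id: dict[str, SpecimenRecord] = {}
    for r in records:
        if r.sample_id in rec_by_id:
            raise ValueError(f"duplicate sample id {r.sample_id!r} in records")
        rec_by_id[r.sample_id] = r
    linked: dict[str, dict[str, BarcodeSequence]] = {}
    orphans: set[str] = set()
    for s in sequences:
        if s.sample_id not in rec_by_id:
            orphans.add(s.sample_id)
            continue
        per = linked.setdefault(s.sample_id, {})
        if s.locus in per:
            raise ValueError(
                f"sample {s.sample_id}: duplicate sequence for {s.locus}")
        per[s.locus] = s
    empty = {sid for sid in rec_by_id if sid not in linked}
    return Library(records=rec_by_id, sequences=linked,
                   orphan_sequence_ids=orphans,
                   records_without_sequences=empty)


# ---------------------------------------------------------------------------
# microinversion normalization
# ---------------------------------------------------------------------------


def _consensus(seqs: list[str], start: int, width: int) -> str:
    """Column-majority consensus over a window; ties break alphabetically."""
    out = []
    for col in range(start, start + width):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[col]] = counts.get(s[col], 0) + 1
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        out.append(best)
    return "".join(out)


@dataclass(frozen=True)
class MicroinversionEdit:
    sample_id: str
    start_column: int  # 1-based, inclusive
    original: str
    replacement: str


def normalize_microinversions(
        matrix: AlignedMatrix,
        window_length: int = 6) -> tuple[AlignedMatrix, list[MicroinversionEdit]]:
    """Reorient rows whose window is the reverse complement of the consensus.

    Short microinversions in non-coding spacers (e.g. the 6-bp inversion in
    psbA-trnH) would otherwise inflate distances and break identity calls.
    A row is edited in a window only when its segment equals the reverse
    complement of the column-majority consensus AND disagrees with the
    consensus in strictly more than half the window's positions — the second
    clause stops windows that equal their own reverse complement (e.g.
    palindromes) from being touched.  Reported column positions are 1-based
    inclusive.  The operation is idempotent.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if window_length > matrix.n_columns:
        raise ValueError(
            f"window_length {window_length} exceeds alignment width "
            f"{matrix.n_columns}")
    seqs = list(matrix.seqs)
    edits: list[MicroinversionEdit] = []
    for start in range(matrix.n_columns - window_length + 1):
        cons = _consensus(seqs, start, window_length)
        rc = reverse_complement(cons)
        for i, s in enumerate(seqs):
            seg = s[start:start + window_length]
            if seg != rc:
                continue
            mismatches = sum(a != b for a, b in zip(seg, cons))
            if mismatches * 2 > window_length:
                seqs[i] = s[:start] + cons + s[start + window_length:]
                edits.append(MicroinversionEdit(
                    sample_id=matrix.ids[i], start_column=start + 1,
                    original=seg, replacement=cons))
    fixed = AlignedMatrix(locus=matrix.locus, scope=matrix.scope,
                          ids=list(matrix.ids), seqs=seqs)
    return fixed, edits
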