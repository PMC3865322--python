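"""Shared fixtures: small hand-built libraries and seeded synthetic ones."""

from __future__ import annotations

import pytest

from barcodekit import (AlignedMatrix, BarcodeSequence, SpecimenRecord, link)
from barcodekit.simulate import SyntheticConfig, generate_library


def make_record(sample_id, family="Poaceae", genus="Poa", species="glauca",
                **kw):
    return SpecimenRecord(sample_id=sample_id, family=family, genus=genus,
                          species=species, **kw)


def make_matrix(rows, locus="rbcL", scope="Poaceae"):
    """rows: list of (sample_id, residues)."""
    return AlignedMatrix(locus=locus, scope=scope,
                         ids=[r[0] for r in rows],
                         seqs=[r[1] for r in rows])


def library_from(rows, locus="rbcL", taxa=None):
    """Build a linked library from (sample_id, residues) rows.

    ``taxa`` maps sample_id to (family, genus, species[, infra, hybrid]).
    """
    taxa = taxa or {}
    records, seqs = [], []
    for sid, residues in rows:
        spec = taxa.get(sid, ("Poaceae", "Poa", sid))
        family, genus, species = spec[:3]
        infra = spec[3] if len(spec) > 3 else None
        hybrid = spec[4] if len(spec) > 4 else False
        records.append(SpecimenRecord(
            sample_id=sid, family=family, genus=genus, species=species,
            infraspecific=infra, is_hybrid=hybrid))
        seqs.append(BarcodeSequence(sample_id=sid, locus=locus,
                                    residues=residues, aligned=True))
    return link(records, seqs)


@pytest.fixture(scope="session")
def small_synthetic():
    """One deterministic mid-sized library with ground truth."""
    cfg = SyntheticConfig(seed=0, n_families=4, p_hybrid=0.0)
    records, sequences, truth = generate_library(cfg)
    return cfg, records, sequences, truth
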