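#!/usr/bin/env python
"""Per-family neighbour-joining phenograms from uncorrected p-distances.

Writes one Newick tree per (family, locus) to results/trees/ and flags
any individual grossly misplaced with respect to its family (all k = 3
nearest neighbours in a different family despite a confamilial
alternative being present) — the validation step used to catch label
swaps and contamination before a library is trusted.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from barcodekit import (distance_matrix, link, nj_tree,
                        write_newick)  # noqa: E402
from barcodekit.io import AlignedMatrix  # noqa: E402
from barcodekit.njtree import drop_undefined, flag_misplaced  # noqa: E402
from barcodekit.simulate import SyntheticConfig, generate_library  # noqa: E402

OUT = ROOT / "results" / "trees"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=seed)
    records, sequences, _ = generate_library(cfg)
    lib = link(records, sequences)

    n_trees = 0
    for locus in cfg.locus_names:
        for family, matrix in lib.matrices(locus).items():
            if matrix.n_rows < 2:
                continue
            dm, dropped = drop_undefined(distance_matrix(matrix))
            if dm.n < 2:
                continue
            write_newick(nj_tree(dm), OUT / f"{family}_{locus}.nwk")
            n_trees += 1
    print(f"{n_trees} NJ trees written to {OUT}")

    # validation: cross-family misplacement scan on the full rbcL matrix
    seqs = [lib.sequences[sid]["rbcL"] for sid in sorted(lib.sequences)
            if "rbcL" in lib.sequences[sid]]
    dm, _ = drop_undefined(
        distance_matrix(AlignedMatrix.from_sequences(seqs,
                                                     scope="combined")))
    flags = flag_misplaced(dm, lib, level="family", k=3)
    print(f"misplaced individuals flagged: {len(flags)}")
    for f in flags:
        print(f"  {f.sample_id} (recorded {f.expected_taxon}): "
              f"nearest = {[(n[0], n[1]) for n in f.neighbors]}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
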