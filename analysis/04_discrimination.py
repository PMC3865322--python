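#!/usr/bin/env python
"""Taxon-discrimination analysis on the synthetic reference library.

Scores genera, species and infraspecific taxa per locus and for the
complete-case rbcL+matK concatenation, aggregates per-family and
per-genus resolution percentages, and — with clade-structured sharing
enabled — measures the correlation between the number of species sampled
per genus and the percent resolved, mirroring the negative correlation
reported for real Arctic libraries.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from barcodekit import (concat_loci, haplotype_discrimination, link,
                        merge_reports, resolution_summary,
                        sampling_resolution_correlation)  # noqa: E402
from barcodekit.simulate import (DropoutSpec, SyntheticConfig,
                                 generate_library,
                                 truncated_geometric)  # noqa: E402

RESULTS = ROOT / "results"
NO_DROPOUT = (("rbcL", DropoutSpec(0.0)), ("matK", DropoutSpec(0.0)))


def score(lib, locus, level):
    if locus == "combined":
        mats_a, mats_b = lib.matrices("rbcL"), lib.matrices("matK")
        reports = []
        for fam in sorted(set(mats_a) & set(mats_b)):
            combined = concat_loci(mats_a[fam], mats_b[fam])
            if combined.n_rows:
                reports.append(haplotype_discrimination(combined, lib,
                                                        level=level))
    else:
        reports = [haplotype_discrimination(m, lib, level=level)
                   for m in lib.matrices(locus).values()]
    return merge_reports(reports)


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    records, sequences, _ = generate_library(SyntheticConfig(seed=seed))
    lib = link(records, sequences)

    rows = []
    for locus in ("rbcL", "matK", "combined"):
        for level in ("genus", "species", "infraspecific"):
            rep = score(lib, locus, level)
            rows.append({"locus": locus, "level": level,
                         "n_taxa": rep.n_taxa,
                         "n_resolved": rep.n_resolved,
                         "percent_resolved": round(rep.percent_resolved, 1)})
            print(f"{locus:9s} {level:14s} {rep.n_resolved:4d}/"
                  f"{rep.n_taxa:<4d} ({rep.percent_resolved:5.1f}%)")
    pd.DataFrame(rows).to_csv(RESULTS / "discrimination_summary.tsv",
                              sep="\t", index=False)

    rep = score(lib, "combined", "species")
    for grouping in ("family", "genus"):
        summ = resolution_summary(rep, lib, grouping=grouping)
        pd.DataFrame(summ.rows, columns=[
            grouping, "n_species_sampled", "n_resolved",
            "percent_resolved"]).to_csv(
            RESULTS / f"resolution_by_{grouping}.tsv", sep="\t", index=False)
    print(f"\nfully resolved genera: {len(summ.fully_resolved)}; "
          f"fully unresolved genera: {len(summ.fully_unresolved)}")

    # clade-structured sharing: larger genera share more
    cfg = SyntheticConfig(
        seed=seed, n_families=15, p_share=0.05, clade_share_slope=0.08,
        species_per_genus=truncated_geometric(3.0, 1, 12),
        p_hybrid=0.0, dropout=NO_DROPOUT)
    records, sequences, _ = generate_library(cfg)
    lib2 = link(records, sequences)
    rep2 = merge_reports([haplotype_discrimination(m, lib2, level="species")
                          for m in lib2.matrices("rbcL").values()])
    summ2 = resolution_summary(rep2, lib2, grouping="genus")
    res = sampling_resolution_correlation(summ2)
    print(f"\nclade-structured sharing: Pearson r = {res.r:.4f} "
          f"(n = {res.n} genera, p = {res.p_value:.3g})")
    print("(the published analysis likewise reports a significant "
          "negative sampling-vs-resolution correlation)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
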