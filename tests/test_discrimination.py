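"""Discrimination scoring: identity rules, both routes, summaries."""

import math

import numpy as np
import pytest

import barcodekit as bk
from barcodekit import (best_match_discrimination, concat_loci,
                        haplotype_discrimination, merge_reports,
                        resolution_summary, sampling_resolution_correlation,
                        sequences_identical)
from barcodekit.discrimination import ResolutionSummary
from barcodekit.distances import site_pair_counts
from barcodekit.simulate import SyntheticConfig, generate_library
from conftest import library_from, make_matrix


# ---------------------------------------------------------------------------
# identity and concatenation
# ---------------------------------------------------------------------------


class TestSequencesIdentical:
    def test_identical_ungapped(self):
        assert sequences_identical("ACGT" * 30, "ACGT" * 30, min_overlap=100)

    def test_one_mismatch_breaks_identity(self):
        a = "ACGT" * 30
        b = "TCGT" + a[4:]
        assert not sequences_identical(a, b, min_overlap=100)

    def test_short_overlap_is_not_identity(self):
        a = "ACGT" * 30
        b = ("ACGT" * 10) + "-" * 80
        # only 40 comparable sites: below the evidence threshold
        assert not sequences_identical(a, b, min_overlap=100)
        assert sequences_identical(a, b, min_overlap=40)


class TestConcatLoci:
    def test_complete_case_intersection(self):
        a = make_matrix([("s1", "AAAA"), ("s2", "CCCC")], locus="rbcL")
        b = make_matrix([("s1", "GGG")], locus="matK")
        combined = concat_loci(a, b)
        assert combined.ids == ["s1"]
        assert combined.seqs == ["AAAAGGG"]

    def test_column_counts_add(self):
        a = make_matrix([("s1", "A" * 500)], locus="rbcL")
        b = make_matrix([("s1", "C" * 800)], locus="matK")
        assert concat_loci(a, b).n_columns == 1300

    def test_scope_mismatch_errors(self):
        a = make_matrix([("s1", "AAAA")], scope="Poaceae")
        b = make_matrix([("s1", "CCCC")], scope="Cyperaceae")
        with pytest.raises(ValueError):
            concat_loci(a, b)

    def test_empty_intersection_warns(self, caplog):
        a = make_matrix([("s1", "AAAA")], locus="rbcL")
        b = make_matrix([("s2", "CCCC")], locus="matK")
        with caplog.at_level("WARNING"):
            combined = concat_loci(a, b)
        assert combined.n_rows == 0

    def test_site_counts_additive_over_loci(self):
        rng = np.random.default_rng(3)
        alpha = "ACGT-N"
        rows_a = [(f"s{i}", "".join(alpha[j]
                                    for j in rng.integers(0, 6, 120)))
                  for i in range(6)]
        rows_b = [(f"s{i}", "".join(alpha[j]
                                    for j in rng.integers(0, 6, 200)))
                  for i in range(6)]
        a, b = make_matrix(rows_a), make_matrix(rows_b, locus="matK")
        combined = concat_loci(a, b)
        for i in range(6):
            for j in range(i + 1, 6):
                ca = site_pair_counts(rows_a[i][1], rows_a[j][1])
                cb = site_pair_counts(rows_b[i][1], rows_b[j][1])
                cc = site_pair_counts(combined.seqs[i], combined.seqs[j])
                assert cc.comparable_sites == \
                    ca.comparable_sites + cb.comparable_sites
                assert cc.mismatches == ca.mismatches + cb.mismatches


# ---------------------------------------------------------------------------
# haplotype route
# ---------------------------------------------------------------------------


def _two_species_library(shared: bool):
    """Species A (2 inds), species B (2 inds); optionally sharing h1."""
    h1 = "ACGT" * 50
    h2 = "TT" + h1[2:]
    rows = [("a1", h1), ("a2", h1),
            ("b1", h1 if shared else h2), ("b2", h2)]
    return library_from(rows, taxa={
        "a1": ("Poaceae", "Poa", "alpina"),
        "a2": ("Poaceae", "Poa", "alpina"),
        "b1": ("Poaceae", "Poa", "glauca"),
        "b2": ("Poaceae", "Poa", "glauca")})


class TestHaplotypeDiscrimination:
    def test_disjoint_haplotypes_both_resolved(self):
        lib = _two_species_library(shared=False)
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="species")
        assert rep.percent_resolved == 100.0

    def test_shared_haplotype_unresolves_both_symmetrically(self):
        lib = _two_species_library(shared=True)
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="species")
        a, b = rep.entries["Poa alpina"], rep.entries["Poa glauca"]
        assert not a.resolved and not b.resolved
        assert a.shared_with == {"Poa glauca"}
        assert b.shared_with == {"Poa alpina"}

    def test_genus_level_unaffected_by_within_genus_sharing(self):
        lib = _two_species_library(shared=True)
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="genus")
        assert rep.entries["Poa"].resolved

    def test_hybrids_excluded(self):
        h1 = "ACGT" * 50
        lib = library_from(
            [("a1", h1), ("x1", h1)],
            taxa={"a1": ("Poaceae", "Poa", "alpina"),
                  "x1": ("Poaceae", "Poa", "glauca", None, True)})
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="species")
        assert list(rep.entries) == ["Poa alpina"]
        assert rep.entries["Poa alpina"].resolved

    def test_infraspecific_scope_needs_two_taxa(self):
        h1 = "ACGT" * 50
        h2 = "TT" + h1[2:]
        lib = library_from(
            [("a1", h1), ("a2", h2), ("b1", h1)],
            taxa={"a1": ("Poaceae", "Poa", "arctica", ("subsp.", "arctica")),
                  "a2": ("Poaceae", "Poa", "arctica", ("subsp.", "caespitans")),
                  "b1": ("Poaceae", "Poa", "glauca", ("subsp.", "glauca"))})
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="infraspecific")
        # Poa glauca has one sampled infraspecific taxon: out of scope
        assert set(rep.entries) == {"Poa arctica subsp. arctica",
                                    "Poa arctica subsp. caespitans"}
        assert all(e.resolved for e in rep.entries.values())

    def test_matches_brute_force_oracle_on_synthetic(self, small_synthetic):
        cfg, records, sequences, _ = small_synthetic
        lib = bk.link(records, sequences)
        for fam, matrix in lib.matrices("rbcL").items():
            rep = haplotype_discrimination(matrix, lib, level="species")
            # independent O(n^2) oracle: raw pair loop, no shared helpers
            rows = [(sid, seq) for sid, seq in matrix.rows
                    if not lib.records[sid].is_hybrid
                    and lib.records[sid].species]
            unresolved = set()
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    si, sj = rows[i], rows[j]
                    ti = lib.records[si[0]].binomial
                    tj = lib.records[sj[0]].binomial
                    if ti == tj:
                        continue
                    comp = mism = 0
                    for x, y in zip(si[1], sj[1]):
                        if x in "ACGT" and y in "ACGT":
                            comp += 1
                            if x != y:
                                mism += 1
                    if mism == 0 and comp >= 100:
                        unresolved |= {ti, tj}
            assert set(rep.unresolved_taxa()) == unresolved


# ---------------------------------------------------------------------------
# best-match route
# ---------------------------------------------------------------------------


class TestBestMatch:
    def test_singleton_with_unique_sequence_discriminated(self):
        h1 = "ACGT" * 50
        h2 = "TT" + h1[2:]
        lib = library_from(
            [("a1", h1), ("b1", h2)],
            taxa={"a1": ("Poaceae", "Poa", "alpina"),
                  "b1": ("Poaceae", "Poa", "glauca")})
        rep = best_match_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                        level="species")
        e = rep.entries["Poa glauca"]
        assert e.singleton and e.resolved
        assert e.rule == "singleton-unique-sequence"

    def test_genus_rule_fires_on_any_cross_genus_identity(self):
        # query q1 has a 100% match in another genus; the rule governs
        # regardless of any same-genus context
        h1 = "ACGT" * 50
        lib = library_from(
            [("q1", h1), ("q2", h1), ("f1", h1)],
            taxa={"q1": ("Poaceae", "Poa", "alpina"),
                  "q2": ("Poaceae", "Poa", "alpina"),
                  "f1": ("Poaceae", "Festuca", "rubra")})
        rep = best_match_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                        level="genus")
        assert not rep.entries["Poa"].resolved
        assert not rep.entries["Festuca"].resolved

    def test_agrees_with_haplotype_route_everywhere(self, small_synthetic):
        cfg, records, sequences, _ = small_synthetic
        lib = bk.link(records, sequences)
        for level in ("genus", "species"):
            for fam, matrix in lib.matrices("matK").items():
                a = haplotype_discrimination(matrix, lib, level=level)
                b = best_match_discrimination(matrix, lib, level=level)
                assert {t: e.resolved for t, e in a.entries.items()} == \
                    {t: e.resolved for t, e in b.entries.items()}


# ---------------------------------------------------------------------------
# summaries and correlation
# ---------------------------------------------------------------------------


class TestResolutionSummary:
    def test_percentages(self):
        lib = _two_species_library(shared=False)
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="species")
        summ = resolution_summary(rep, lib, grouping="family")
        assert summ.as_dict()["Poaceae"] == (2, 2, 100.0)
        assert summ.fully_resolved == ["Poaceae"]

    def test_extremes_lists(self):
        lib = _two_species_library(shared=True)
        rep = haplotype_discrimination(lib.matrix("rbcL", "Poaceae"), lib,
                                       level="species")
        summ = resolution_summary(rep, lib, grouping="genus")
        assert summ.fully_unresolved == ["Poa"]

    def test_matches_generator_bookkeeping(self, small_synthetic):
        cfg, records, sequences, truth = small_synthetic
        lib = bk.link(records, sequences)
        reports = [haplotype_discrimination(m, lib, level="species")
                   for m in lib.matrices("rbcL").values()]
        rep = merge_reports(reports)
        summ = resolution_summary(rep, lib, grouping="genus")
        unresolved = truth.unresolved_species("rbcL")
        for genus, (n, r, pct) in summ.as_dict().items():
            scored = {t for t in rep.entries
                      if truth.species_parent.get(t, ("",))[0] == genus}
            expect_resolved = len(scored - unresolved)
            assert r == expect_resolved

    def test_order_and_renaming_invariance(self):
        h1 = "ACGT" * 50
        h2 = "TT" + h1[2:]
        rows = [("a1", h1), ("b1", h2), ("b2", h1)]
        taxa = {"a1": ("Poaceae", "Poa", "alpina"),
                "b1": ("Poaceae", "Poa", "glauca"),
                "b2": ("Poaceae", "Poa", "glauca")}
        lib1 = library_from(rows, taxa=taxa)
        lib2 = library_from(rows[::-1], taxa=taxa)
        r1 = haplotype_discrimination(lib1.matrix("rbcL", "Poaceae"), lib1,
                                      level="species")
        r2 = haplotype_discrimination(lib2.matrix("rbcL", "Poaceae"), lib2,
                                      level="species")
        assert {t: e.resolved for t, e in r1.entries.items()} == \
            {t: e.resolved for t, e in r2.entries.items()}


class TestSamplingResolutionCorrelation:
    def test_zero_variance_flagged(self):
        summ = ResolutionSummary(grouping="genus", rows=[
            ("A", 1, 1, 100.0), ("B", 2, 2, 100.0), ("C", 3, 3, 100.0)])
        res = sampling_resolution_correlation(summ)
        assert res.flagged and math.isnan(res.r)

    def test_exact_descending_line(self):
        summ = ResolutionSummary(grouping="genus", rows=[
            ("A", 1, 1, 100.0), ("B", 2, 1, 50.0), ("C", 3, 0, 0.0)])
        res = sampling_resolution_correlation(summ)
        assert res.r == pytest.approx(-1.0)

    def test_requires_genus_grouping(self):
        summ = ResolutionSummary(grouping="family", rows=[])
        with pytest.raises(ValueError):
            sampling_resolution_correlation(summ)


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------


class TestMonotonicity:
    def test_concatenation_never_destroys_resolution(self):
        """Non-identical on locus A stays non-identical on A+B."""
        cfg = SyntheticConfig(seed=6, n_families=3, p_hybrid=0.0)
        records, sequences, _ = generate_library(cfg)
        lib = bk.link(records, sequences)
        mats_a, mats_b = lib.matrices("rbcL"), lib.matrices("matK")
        for fam in set(mats_a) & set(mats_b):
            combined = concat_loci(mats_a[fam], mats_b[fam])
            if combined.n_rows < 2:
                continue
            shared_ids = set(combined.ids)
            sub_a = make_matrix(
                [(sid, mats_a[fam].row(sid)) for sid in combined.ids],
                locus="rbcL", scope=fam)
            rep_a = haplotype_discrimination(sub_a, lib, level="species")
            rep_ab = haplotype_discrimination(combined, lib, level="species")
            for taxon, e in rep_a.entries.items():
                if e.resolved:
                    assert rep_ab.entries[taxon].resolved, taxon

    def test_disjoint_vs_fully_shared_extremes(self):
        """Disjoint haplotype sets -> 100% species resolution; one haplotype
        shared across every congener -> 0% species but 100% genus."""
        h = "ACGT" * 50
        variants = [h, "TT" + h[2:], "GG" + h[2:], "AA" + h[2:]]
        taxa = {f"s{i}": ("Poaceae", "Poa", f"sp{i}") for i in range(4)}
        disjoint = library_from(
            [(f"s{i}", variants[i]) for i in range(4)], taxa=taxa)
        rep = haplotype_discrimination(
            disjoint.matrix("rbcL", "Poaceae"), disjoint, level="species")
        assert rep.percent_resolved == 100.0
        shared = library_from(
            [(f"s{i}", h) for i in range(4)], taxa=taxa)
        rep_sp = haplotype_discrimination(
            shared.matrix("rbcL", "Poaceae"), shared, level="species")
        rep_gen = haplotype_discrimination(
            shared.matrix("rbcL", "Poaceae"), shared, level="genus")
        assert rep_sp.percent_resolved == 0.0
        assert rep_gen.percent_resolved == 100.0
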