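"""Neighbour joining: exactness on additive matrices, determinism, flags."""

import itertools
import math

import numpy as np
import pytest

from barcodekit import link, nearest_neighbors, nj_tree
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.io import SpecimenRecord, UnrootedTree
from barcodekit.njtree import drop_undefined, flag_misplaced
from barcodekit.simulate import SyntheticConfig, generate_library


def dm_from(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=list(ids), d=d,
                          comparable=np.full(d.shape, 500))


def random_tree_distances(labels, rng):
    """Random unrooted binary tree with positive lengths; returns
    (tree, leaf-to-leaf distance DataFrame)."""
    t = UnrootedTree()
    nodes = [t.add_node(lab) for lab in labels[:3]]
    hub = t.add_node()
    edges = []
    for n in nodes:
        length = rng.uniform(0.5, 3.0)
        t.add_edge(n, hub, length)
        edges.append((n, hub))
    for lab in labels[3:]:
        u, v = edges[rng.integers(len(edges))]
        w = t._adj[u][v]
        split = t.add_node()
        del t._adj[u][v], t._adj[v][u]
        cut = rng.uniform(0.25, 0.75) * w
        t.add_edge(u, split, cut)
        t.add_edge(split, v, w - cut)
        leaf = t.add_node(lab)
        t.add_edge(leaf, split, rng.uniform(0.5, 3.0))
        edges.remove((u, v))
        edges += [(u, split), (split, v), (leaf, split)]
    _, plm = t.path_length_matrix()
    return t, plm


class TestNJ:
    def test_two_samples_single_edge(self):
        t = nj_tree(dm_from(["a", "b"], [[0, 0.1], [0.1, 0]]))
        _, plm = t.path_length_matrix()
        assert plm.loc["a", "b"] == pytest.approx(0.1)

    def test_four_taxon_example_recovers_split_and_lengths(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = nj_tree(dm_from("ABCD", d))
        assert t.splits() in ({frozenset("CD")}, {frozenset("AB")})
        _, plm = t.path_length_matrix()
        expect = np.array(d, float)
        assert np.allclose(plm.values, expect, atol=1e-9)
        # four-point condition on the recovered path lengths
        ab_cd = plm.loc["A", "B"] + plm.loc["C", "D"]
        ac_bd = plm.loc["A", "C"] + plm.loc["B", "D"]
        ad_bc = plm.loc["A", "D"] + plm.loc["B", "C"]
        assert ab_cd <= min(ac_bd, ad_bc) + 1e-9
        assert ac_bd == pytest.approx(ad_bc)

    def test_five_taxon_topology_vs_exhaustive_search(self):
        """NJ must pick the unique additive topology among all 15."""
        rng = np.random.default_rng(5)
        labels = list("ABCDE")
        true_tree, plm = random_tree_distances(labels, rng)
        got = nj_tree(dm_from(labels, plm.values))
        assert got.splits() == true_tree.splits()
        # brute force: the true splits minimize path-length discrepancy 0
        _, got_plm = got.path_length_matrix()
        assert np.allclose(got_plm.values, plm.values, atol=1e-9)

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(17)
        for rep in range(20):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            true_tree, plm = random_tree_distances(labels, rng)
            got = nj_tree(dm_from(labels, plm.values))
            assert got.splits() == true_tree.splits()
            _, got_plm = got.path_length_matrix()
            assert np.abs(got_plm.values - plm.values).max() < 1e-9

    def test_edge_count_and_leaf_set(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(7)]
        _, plm = random_tree_distances(labels, rng)
        t = nj_tree(dm_from(labels, plm.values))
        assert t.leaf_labels == sorted(labels)
        assert t.n_edges() == 2 * 7 - 3

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(6)]
        _, plm = random_tree_distances(labels, rng)
        t1 = nj_tree(dm_from(labels, plm.values))
        perm = list(rng.permutation(6))
        t2 = nj_tree(dm_from([labels[i] for i in perm],
                             plm.values[np.ix_(perm, perm)]))
        assert t1.splits() == t2.splits()
        _, p1 = t1.path_length_matrix()
        _, p2 = t2.path_length_matrix()
        assert np.allclose(p1.values, p2.values, atol=1e-12)

    def test_matches_scikit_bio_on_additive_input(self):
        import io as _io
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(31)
        labels = [f"t{i}" for i in range(7)]
        _, plm = random_tree_distances(labels, rng)
        sym = (plm.values + plm.values.T) / 2  # exact symmetry for skbio
        ours = nj_tree(dm_from(labels, sym))
        ref = skbio_nj(SkbioDM(sym, ids=labels))
        for a, b in itertools.combinations(labels, 2):
            _, our_plm = ours.path_length_matrix()
            assert ref.find(a).distance(ref.find(b)) == pytest.approx(
                our_plm.loc[a, b], abs=1e-9)

    def test_undefined_distances_are_an_error(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm_from(["a", "b"], d))

    def test_drop_undefined_iterative(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        cleaned, dropped = drop_undefined(dm_from(["a", "b", "c"], d))
        assert len(dropped) == 1
        assert not np.isnan(cleaned.d).any()


class TestNearestNeighbors:
    def test_single_nearest(self):
        d = [[0, 0.01, 0.02], [0.01, 0, 0.05], [0.02, 0.05, 0]]
        dm = dm_from(["s1", "s2", "s3"], d)
        assert nearest_neighbors(dm, "s1", k=1) == [("s2", 0.01)]

    def test_tie_breaks_lexicographically(self):
        d = [[0, 0.01, 0.01], [0.01, 0, 0.05], [0.01, 0.05, 0]]
        dm = dm_from(["s1", "s3", "s2"], d)
        assert nearest_neighbors(dm, "s1", k=1) == [("s2", 0.01)]

    def test_k_exceeding_pool_returns_all(self, caplog):
        d = [[0, 0.01], [0.01, 0]]
        dm = dm_from(["s1", "s2"], d)
        with caplog.at_level("WARNING"):
            got = nearest_neighbors(dm, "s1", k=5)
        assert got == [("s2", 0.01)]
        assert "only 1" in caplog.text

    def test_agrees_with_full_sort(self):
        rng = np.random.default_rng(13)
        n = 12
        raw = rng.uniform(0.001, 0.5, (n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i:02d}" for i in range(n)]
        dm = dm_from(ids, d)
        got = nearest_neighbors(dm, "s00", k=5)
        expect = sorted(((d[0, j], ids[j]) for j in range(1, n)))[:5]
        assert got == [(sid, val) for val, sid in expect]


class TestFlagMisplaced:
    def _library(self, taxa):
        recs = [SpecimenRecord(sample_id=s, family=f, genus=g, species=sp)
                for s, (f, g, sp) in taxa.items()]
        return link(recs, [])

    def test_planted_outlier_is_flagged(self):
        # p1 sits sequence-wise among Cyperaceae; its congener p2 is distant
        taxa = {"c1": ("Cyperaceae", "Carex", "aquatilis"),
                "c2": ("Cyperaceae", "Carex", "bigelowii"),
                "c3": ("Cyperaceae", "Eriophorum", "vaginatum"),
                "p1": ("Poaceae", "Poa", "glauca"),
                "p2": ("Poaceae", "Poa", "glauca")}
        ids = list(taxa)
        d = np.full((5, 5), 0.30)
        np.fill_diagonal(d, 0)
        for i in range(3):  # the Cyperaceae cluster
            for j in range(3):
                if i != j:
                    d[i, j] = 0.01
        d[3, :3] = d[:3, 3] = 0.012  # p1 planted inside the cluster
        d[3, 4] = d[4, 3] = 0.25     # p2's nearest neighbour is its congener
        lib = self._library(taxa)
        flags = flag_misplaced(dm_from(ids, d), lib, level="family", k=3)
        assert [f.sample_id for f in flags] == ["p1"]
        assert all(t == "Cyperaceae" for _, t, _ in flags[0].neighbors)

    def test_monotypic_genus_never_flagged(self):
        taxa = {"a": ("Poaceae", "Poa", "glauca"),
                "b": ("Poaceae", "Festuca", "rubra"),
                "c": ("Poaceae", "Poa", "alpina")}
        d = [[0, 0.01, 0.3], [0.01, 0, 0.3], [0.3, 0.3, 0]]
        lib = self._library(taxa)
        flags = flag_misplaced(dm_from(list(taxa), d), lib,
                               level="genus", k=1)
        # b (monotypic Festuca) has no congeneric alternative
        assert "b" not in {f.sample_id for f in flags}

    def test_planted_label_swaps_found_exactly(self):
        """Swap family labels of 5 individuals; flags recover exactly them."""
        from barcodekit.simulate import DropoutSpec
        cfg = SyntheticConfig(seed=4, n_families=5, p_share=0.0,
                              p_hybrid=0.0,
                              dropout=(("rbcL", DropoutSpec(0.0)),
                                       ("matK", DropoutSpec(0.0))))
        records, sequences, _ = generate_library(cfg)
        by_fam: dict[str, list] = {}
        for r in records:
            by_fam.setdefault(r.family, []).append(r)
        fams = sorted(by_fam)
        swapped = []
        new_records = {r.sample_id: r for r in records}
        for i, fam in enumerate(fams):
            donor = by_fam[fams[(i + 1) % len(fams)]][0]
            victim = by_fam[fam][-1]
            swapped.append(victim.sample_id)
            new_records[victim.sample_id] = SpecimenRecord(
                sample_id=victim.sample_id, family=donor.family,
                genus=donor.genus, species=donor.species)
        lib = link(new_records.values(),
                   [s for s in sequences if s.locus == "rbcL"])
        from barcodekit.io import AlignedMatrix
        seqs = [lib.sequences[sid]["rbcL"] for sid in sorted(lib.sequences)
                if "rbcL" in lib.sequences[sid]]
        matrix = AlignedMatrix.from_sequences(seqs, scope="combined")
        dm = distance_matrix(matrix, min_overlap=50)
        flags = flag_misplaced(dm, lib, level="family", k=3)
        assert {f.sample_id for f in flags} == set(swapped)
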