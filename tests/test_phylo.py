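import numpy as np
import pytest

import numt_sieve as ns
from numt_sieve.errors import DataError
from numt_sieve.phylo import bipartition_supports


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


def random_additive_matrix(n_taxa: int, rng):
    """Distances generated by a random binary tree with positive edges."""
    import dendropy
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=tns, rng=rng)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(1e-3 + rng.random())
    pdm = tree.phylogenetic_distance_matrix()
    ids = [t.label for t in tns]
    d = np.zeros((n_taxa, n_taxa))
    taxa = {t.label: t for t in tns}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
    return ns.DistanceMatrix(ids=ids, d=d)


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(DataError):
            ns.DistanceMatrix(ids=["a", "b"], d=np.array([[0, 1], [2, 0]], float))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(DataError):
            ns.DistanceMatrix(ids=["a", "b"], d=np.array([[1, 1], [1, 0]], float))

    def test_phylip_round_trip(self):
        dm = ns.DistanceMatrix(ids=["a", "b", "c"],
                               d=np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]))
        back = ns.DistanceMatrix.from_phylip(dm.to_phylip())
        assert back.ids == dm.ids
        np.testing.assert_allclose(back.d, dm.d, atol=1e-10)


class TestNeighborJoining:
    def test_three_taxon_pendant_lengths(self):
        dm = ns.DistanceMatrix(ids=["A", "B", "C"],
                               d=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = ns.nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_two_taxa_single_edge(self):
        dm = ns.DistanceMatrix(ids=["A", "B"], d=np.array([[0, .1], [.1, 0]]))
        tree = ns.nj_tree(dm)
        dist = patristic(tree)
        assert dist("A", "B") == pytest.approx(0.1)

    def test_additive_matrix_recovery(self):
        """On additive distances NJ reproduces the generating tree's path
        lengths (random trees up to 8 taxa)."""
        import random
        rng = random.Random(13)
        for n_taxa in (4, 5, 6, 8):
            dm = random_additive_matrix(n_taxa, rng)
            tree = ns.nj_tree(dm)
            dist = patristic(tree)
            for i, a in enumerate(dm.ids):
                for j in range(i + 1, len(dm.ids)):
                    assert dist(a, dm.ids[j]) == pytest.approx(
                        dm.d[i, j], abs=1e-9)


class TestBootstrapConsensus:
    @pytest.fixture(scope="class")
    def clean_alignment(self):
        # six mildly diverged relatives: K2P stays well inside its domain
        # even under column resampling
        recs = ns.generate_synthetic_community(6, length=120, seed=81,
                                               divergence=0.06)
        return ns.Alignment([ns.aligned_record(r.id, r.seq, "nt") for r in recs])

    def test_same_seed_gives_identical_supports(self, clean_alignment):
        t1 = ns.bootstrap_consensus(clean_alignment, n_reps=30, seed=4)
        t2 = ns.bootstrap_consensus(clean_alignment, n_reps=30, seed=4)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_match_recount_of_replicate_trees(self, clean_alignment):
        trees, _ = ns.bootstrap_trees(clean_alignment, 50, seed=6)
        supports = bipartition_supports(trees)
        cons = ns.bootstrap_consensus(clean_alignment, n_reps=50, seed=6)
        all_labels = frozenset(t.label for t in cons.taxon_namespace)
        checked = 0
        for node in cons.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            key = min((side, all_labels - side), key=lambda s: (len(s), sorted(s)))
            assert node.support_pct == pytest.approx(supports[key])
            assert 0 <= node.support_pct <= 100
            assert node.support_pct > 50  # majority rule
            checked += 1
        assert checked >= 1

    def test_perfectly_supported_split(self):
        rows = [ns.aligned_record(i, s, "nt") for i, s in
                [("A", "A" * 60), ("B", "A" * 60),
                 ("C", "G" * 12 + "A" * 48), ("D", "G" * 12 + "A" * 48)]]
        cons = ns.bootstrap_consensus(ns.Alignment(rows), n_reps=25, seed=9)
        internal = [n for n in cons.preorder_internal_node_iter()
                    if n.parent_node is not None]
        assert internal and all(n.support_pct == 100.0 for n in internal)


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        dm = ns.DistanceMatrix(ids=["A", "B"], d=np.array([[0, 1.0], [1.0, 0]]))
        rooted = ns.midpoint_root(ns.nj_tree(dm))
        depths = {lf.taxon.label: lf.distance_from_root()
                  for lf in rooted.leaf_node_iter()}
        assert depths["A"] == pytest.approx(0.5)
        assert depths["B"] == pytest.approx(0.5)

    def test_root_bisects_longest_path(self):
        import random
        dm = random_additive_matrix(6, random.Random(3))
        rooted = ns.midpoint_root(ns.nj_tree(dm))
        depths = [lf.distance_from_root() for lf in rooted.leaf_node_iter()]
        half_diameter = dm.d.max() / 2
        assert max(depths) == pytest.approx(half_diameter, abs=1e-9)


class TestNewickIO:
    def test_round_trip_topology_lengths_supports(self, tmp_path):
        dm = ns.DistanceMatrix(ids=["A", "B", "C"],
                               d=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = ns.nj_tree(dm)
        p = tmp_path / "t.nwk"
        ns.write_newick(tree, p)
        back = ns.read_newick(p)
        d1, d2 = patristic(tree), patristic(back)
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            assert d2(a, b) == pytest.approx(d1(a, b), rel=1e-9)

    def test_supports_survive_round_trip(self, tmp_path):
        rows = [ns.aligned_record(i, s, "nt") for i, s in
                [("A", "A" * 60), ("B", "A" * 60),
                 ("C", "G" * 12 + "A" * 48), ("D", "G" * 12 + "A" * 48)]]
        cons = ns.bootstrap_consensus(ns.Alignment(rows), n_reps=20, seed=2)
        p = tmp_path / "c.nwk"
        ns.write_newick(cons, p)
        back = ns.read_newick(p)
        sup = [n.support_pct for n in back.preorder_internal_node_iter()
               if getattr(n, "support_pct", None) is not None]
        assert sup and all(s == 100.0 for s in sup)

    def test_bare_two_leaf_newick(self, tmp_path):
        p = tmp_path / "b.nwk"
        p.write_text("(A,B);\n")
        tree = ns.read_newick(p)
        assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == ["A", "B"]

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A,B);;;(")
        with pytest.raises(DataError, match="Newick"):
            ns.read_newick(p)
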