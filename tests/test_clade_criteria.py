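import numpy as np
import pandas as pd
import pytest

import v4clades as v
from tree_oracles import (
    graph_distance_matrix,
    graph_splits,
    monophyly_bruteforce,
    random_topology_newick,
    random_tree_graph,
    supported_tree_splits,
)


class TestMonophyly:
    def test_simple_quartet(self):
        tree = v.parse_newick("((A,B),(C,D));")
        assert v.is_monophyletic(tree, {"A", "B"})[0]
        assert not v.is_monophyletic(tree, {"A", "C"})[0]

    def test_complement_side_counts(self):
        # {C,D,E} sits across the root of this rooted representation
        tree = v.parse_newick("((A,B),((C,D),E));")
        assert v.is_monophyletic(tree, {"C", "D", "E"})[0]

    def test_singleton_is_monophyletic(self):
        tree = v.parse_newick("((A,B),(C,D));")
        assert v.is_monophyletic(tree, {"A"})[0]

    def test_unknown_leaf_and_full_set_rejected(self):
        tree = v.parse_newick("((A,B),(C,D));")
        with pytest.raises(KeyError):
            v.is_monophyletic(tree, {"A", "Z"})
        with pytest.raises(ValueError):
            v.is_monophyletic(tree, {"A", "B", "C", "D"})

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(7)
        nwk, names = random_topology_newick(rng, 8)
        tree = v.parse_newick(nwk)
        members = {"L1", "L2", "L3"}
        expected = v.is_monophyletic(tree, members)[0]
        dtree = tree.tree
        node = next(n for n in dtree.leaf_node_iter() if n.taxon.label == "L5")
        dtree.reroot_at_edge(node.edge, update_bipartitions=False)
        rerooted = v.SupportedTree(dtree, "percent")
        assert v.is_monophyletic(rerooted, members)[0] == expected


class TestCladeSupport:
    def test_supports_read_from_defining_edges(self):
        tree = v.parse_newick("((A,B)90,(C,D)85);")
        assert v.clade_support(tree, {"A", "B"}) == 90
        assert v.clade_support(tree, {"C", "D"}) == 85

    def test_absent_support_reported_absent(self):
        tree = v.parse_newick("((A,B),(C,D)75,E);")
        assert v.clade_support(tree, {"A", "B"}) is None

    def test_root_bipartition_support_shared_across_both_root_edges(self):
        # on a rooted-binary representation {A,B}|{C,D} is one unrooted edge
        tree = v.parse_newick("((A,B),(C,D)75);")
        assert v.clade_support(tree, {"A", "B"}) == 75

    def test_posterior_scale_value(self):
        tree = v.parse_newick("((A,B)0.99,C);", scale="probability")
        assert v.clade_support(tree, {"A", "B"}) == pytest.approx(0.99)

    def test_non_monophyletic_members_rejected(self):
        tree = v.parse_newick("((A,B)90,(C,D)85);")
        with pytest.raises(ValueError):
            v.clade_support(tree, {"A", "C"})


class TestEvaluateClade:
    ml = "((A,B)90,((C,D)65,E)80);"
    bayes = "((A,B)0.99,((C,E)0.9,D)0.95);"

    def test_passes_with_dual_monophyly_and_high_support(self):
        verdict = v.evaluate_clade(
            v.parse_newick(self.ml), v.parse_newick(self.bayes, "probability"), {"A", "B"}
        )
        assert verdict.passes and verdict.support_ml == 90

    def test_low_bootstrap_fails(self):
        ml = v.parse_newick("((A,B)65,(C,D));")
        bayes = v.parse_newick("((A,B)0.99,(C,D));", "probability")
        verdict = v.evaluate_clade(ml, bayes, {"A", "B"})
        assert verdict.monophyletic_ml and verdict.monophyletic_bayes
        assert not verdict.passes

    def test_bootstrap_floor_is_strict(self):
        ml = v.parse_newick("((A,B)70,(C,D));")
        bayes = v.parse_newick("((A,B),(C,D));", "probability")
        assert not v.evaluate_clade(ml, bayes, {"A", "B"}).passes
        ml71 = v.parse_newick("((A,B)71,(C,D));")
        assert v.evaluate_clade(ml71, bayes, {"A", "B"}).passes

    def test_single_method_monophyly_fails(self):
        verdict = v.evaluate_clade(
            v.parse_newick(self.ml), v.parse_newick(self.bayes, "probability"), {"C", "D"}
        )
        assert verdict.monophyletic_ml and not verdict.monophyletic_bayes
        assert not verdict.passes

    def test_passing_implies_dual_monophyly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            nwk1, _ = random_topology_newick(rng, 6, with_supports=True)
            nwk2, _ = random_topology_newick(rng, 6, with_supports=True)
            t1, t2 = v.parse_newick(nwk1), v.parse_newick(nwk2)
            members = {"L1", "L2"}
            verdict = v.evaluate_clade(t1, t2, members)
            if verdict.passes:
                assert v.is_monophyletic(t1, members)[0]
                assert v.is_monophyletic(t2, members)[0]

    def test_missing_member_error_names_tree(self):
        ml = v.parse_newick("((A,B),(C,D));")
        bayes = v.parse_newick("((A,B),C);")
        with pytest.raises(KeyError, match="bayes"):
            v.evaluate_clade(ml, bayes, {"A", "D"})


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = v.nj_tree(d)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_star_matrix_gives_zero_internal_branches(self):
        labels = list("ABCDE")
        d = pd.DataFrame(2.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        tree = v.nj_tree(d)
        internal = [
            n.edge.length
            for n in tree.tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert all(abs(x) < 1e-9 for x in internal)

    def test_additive_five_taxon_path_lengths_reproduced(self):
        rng = np.random.default_rng(17)
        g, leaves = random_tree_graph(rng, 5)
        d = graph_distance_matrix(g, leaves)
        tree = v.nj_tree(d)
        paths = v.path_length_matrix(tree).loc[sorted(leaves), sorted(leaves)]
        expected = d.loc[sorted(leaves), sorted(leaves)]
        assert np.allclose(paths.to_numpy(), expected.to_numpy(), atol=1e-9)
        assert supported_tree_splits(tree) == graph_splits(g, leaves)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [9, 0, 2], [2, 2, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            v.nj_tree(d)

    def test_nonzero_diagonal_rejected(self):
        d = pd.DataFrame(
            [[1, 1, 2], [1, 0, 2], [2, 2, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError, match="diagonal"):
            v.nj_tree(d)

    def test_deterministic_output(self):
        rng = np.random.default_rng(23)
        g, leaves = random_tree_graph(rng, 6)
        d = graph_distance_matrix(g, leaves)
        assert v.nj_tree(d).to_newick() == v.nj_tree(d).to_newick()


class TestBruteforceAgreement:
    def test_monophyly_matches_enumeration_on_small_trees(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            nwk, names = random_topology_newick(rng, n)
            tree = v.parse_newick(nwk)
            for _ in range(5):
                k = int(rng.integers(1, n))
                members = set(rng.choice(names, size=k, replace=False))
                assert (
                    v.is_monophyletic(tree, members)[0]
                    == monophyly_bruteforce(tree, members)
                )
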