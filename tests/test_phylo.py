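"""Tree structures, Newick I/O, bipartitions, and tree statistics."""

import math

import dendropy
import numpy as np
import pytest

from branchscore.phylo import (
    Bipartition,
    Tree,
    TreeError,
    NewickParseError,
    bipartition_in_tree,
    extract_bipartitions,
    mad_ultrametricity,
    parse_newick,
    robinson_foulds,
    subtree_side_stats,
    transfer_distance,
    tree_branch_stats,
)
from branchscore.seqsim import SimulationConfig, sample_tree


class TestNewick:
    def test_four_leaf_tree(self, quartet):
        assert quartet.n_leaves == 4
        assert len(quartet.internal_edge_nodes()) == 1

    def test_two_leaf_tree(self):
        t = parse_newick("(A:1,B:2);")
        assert t.n_leaves == 2
        assert t.internal_edge_nodes() == []
        assert t.total_divergence() == pytest.approx(3.0)

    def test_duplicate_label_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B),(A,C));")

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1;")

    @pytest.mark.parametrize("seed", range(6))
    def test_roundtrip_preserves_splits_and_divergence(self, seed):
        tree = sample_tree(int(np.random.default_rng(seed).integers(5, 20)),
                           SimulationConfig(), seed)
        text = tree.to_newick()
        back = parse_newick(text)
        # compare as canonical split sets
        assert set(extract_bipartitions(tree)) == set(extract_bipartitions(back))
        assert back.total_divergence() == pytest.approx(
            tree.total_divergence(), abs=1e-9
        )

    def test_missing_lengths_default_zero(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.total_divergence() == 0.0


class TestBipartitions:
    def test_quartet_split(self, quartet):
        bips = extract_bipartitions(quartet)
        assert len(bips) == 1
        assert bips[0].smaller_side in ({"A", "B"}, {"C", "D"})

    def test_canonical_equality_side_independent(self):
        taxa = {"A", "B", "C", "D", "E"}
        assert Bipartition({"A", "B"}, taxa) == Bipartition({"C", "D", "E"}, taxa)
        assert hash(Bipartition({"A", "B"}, taxa)) == hash(
            Bipartition({"C", "D", "E"}, taxa)
        )

    @pytest.mark.parametrize("ntaxa", [4, 6, 10, 25])
    def test_count_is_n_minus_3(self, ntaxa):
        tree = sample_tree(ntaxa, SimulationConfig(), ntaxa)
        assert len(extract_bipartitions(tree)) == ntaxa - 3

    def test_count_over_many_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            tree = sample_tree(n, SimulationConfig(), int(rng.integers(2**31)))
            assert len(extract_bipartitions(tree)) == n - 3

    def test_membership(self, quartet):
        taxa = set(quartet.labels)
        assert bipartition_in_tree(Bipartition({"A", "B"}, taxa), quartet)
        assert not bipartition_in_tree(Bipartition({"A", "C"}, taxa), quartet)

    def test_membership_requires_same_taxa(self, quartet):
        with pytest.raises(TreeError):
            bipartition_in_tree(Bipartition({"A"}, {"A", "B", "X"}), quartet)

    def test_own_bipartitions_are_members(self):
        tree = sample_tree(12, SimulationConfig(), 5)
        for b in extract_bipartitions(tree):
            assert bipartition_in_tree(b, tree)


def _transfer_oracle(bip: Bipartition, newick: str) -> int:
    """Brute force via dendropy bipartitions: min Hamming over internal
    splits and both side pairings, capped at p-1."""
    dt = dendropy.Tree.get(data=newick, schema="newick")
    taxa = [lf.taxon.label for lf in dt.leaf_node_iter()]
    n = len(taxa)
    side = bip.side
    best = None
    dt.encode_bipartitions()
    for edge in dt.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.tail_node is None:
            continue
        leafset = {
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        }
        if len(leafset) in (0, n):
            continue
        if len(leafset) < 2 or n - len(leafset) < 2:
            continue
        h = len(leafset ^ side)
        d = min(h, n - h)
        best = d if best is None else min(best, d)
    p = bip.p
    return min(best, p - 1) if best is not None else p - 1


class TestTransferDistance:
    def test_present_split_distance_zero(self, quartet):
        for b in extract_bipartitions(quartet):
            assert transfer_distance(b, quartet) == 0

    def test_spec_example(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        bip = Bipartition({"A", "C"}, set("ABCDE"))
        assert transfer_distance(bip, tree) == 1

    def test_symmetric_in_sides(self):
        tree = sample_tree(8, SimulationConfig(), 3)
        taxa = set(tree.labels)
        side = set(list(sorted(taxa))[:3])
        d1 = transfer_distance(Bipartition(side, taxa), tree)
        d2 = transfer_distance(Bipartition(taxa - side, taxa), tree)
        assert d1 == d2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tree = sample_tree(int(rng.integers(5, 12)), SimulationConfig(),
                           int(rng.integers(2**31)))
        taxa = set(tree.labels)
        k = int(rng.integers(2, len(taxa) - 1))
        side = set(rng.choice(sorted(taxa), size=k, replace=False))
        if len(taxa - side) < 2:
            side.pop()
        bip = Bipartition(side, taxa)
        assert transfer_distance(bip, tree) == _transfer_oracle(
            bip, tree.to_newick()
        )


class TestTreeStats:
    def test_degenerate_equal_lengths(self):
        t = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        # derooting merges the two basal edges: lengths 0.1 x4 and 0.2
        s = tree_branch_stats(parse_newick("(A:0.1,B:0.1,(C:0.1,D:0.1):0.1);"))
        assert s.median == pytest.approx(0.1)
        assert s.variance == pytest.approx(0.0)
        assert s.skewness == 0.0 and s.kurtosis == 0.0

    def test_simple_numbers(self):
        t = parse_newick("(A:1,B:2,(C:3,D:4):0.5);")
        s = tree_branch_stats(t)
        assert s.total_divergence == pytest.approx(10.5)
        assert s.median == pytest.approx(2.0)

    def test_moments_match_direct_recomputation(self):
        tree = sample_tree(15, SimulationConfig(), 9)
        x = tree.edge_lengths()
        s = tree_branch_stats(tree)
        assert s.variance == pytest.approx(np.var(x))
        m, sd = x.mean(), x.std()
        assert s.skewness == pytest.approx(np.mean(((x - m) / sd) ** 3))
        assert s.kurtosis == pytest.approx(np.mean(((x - m) / sd) ** 4) - 3)
        assert s.q25 <= s.median <= s.q75


class TestMAD:
    def test_ultrametric_tree_scores_zero(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert mad_ultrametricity(t) == pytest.approx(0.0, abs=1e-12)

    def test_two_leaf_closed_form(self):
        t = parse_newick("(A:1,B:3);")
        assert mad_ultrametricity(t) == pytest.approx(0.5)

    def test_scale_invariance(self):
        tree = sample_tree(10, SimulationConfig(), 11)
        a = mad_ultrametricity(tree)
        tree2 = tree.copy()
        tree2.blen = tree2.blen * 7.3
        assert mad_ultrametricity(tree2) == pytest.approx(a, rel=1e-9)

    def test_bounded_unit_interval(self):
        for seed in range(5):
            tree = sample_tree(8, SimulationConfig(rate_noise_sigma=1.0), seed)
            assert 0.0 <= mad_ultrametricity(tree) <= 1.0


class TestSideStats:
    def test_cherry_side(self, quartet):
        bip = Bipartition({"A", "B"}, set(quartet.labels))
        count, frac, div, divfrac = subtree_side_stats(bip, quartet)
        assert count == 2
        assert frac == pytest.approx(0.5)
        assert div == pytest.approx(0.3)

    def test_matches_brute_force_on_random_tree(self):
        tree = sample_tree(12, SimulationConfig(), 21)
        total = tree.total_divergence()
        masks = tree.subtree_masks()

        def leafset(u):
            return frozenset(tree.labels[i] for i in np.flatnonzero(masks[u]))

        for bip in extract_bipartitions(tree):
            count, frac, div, divfrac = subtree_side_stats(bip, tree)
            side = bip.smaller_side
            assert count == len(side)
            assert frac == pytest.approx(len(side) / tree.n_leaves)
            # brute force: an unrooted edge lies inside the smaller side
            # iff both its endpoints' leaf "shadows" fall within the side
            edge = next(
                x
                for x in tree.internal_edge_nodes()
                if leafset(x) in (side, frozenset(tree.labels) - side)
            )
            inner = sum(
                tree.edge_length(u)
                for u in tree.edge_nodes()
                if u != edge and leafset(u) <= leafset(edge)
            )
            if leafset(edge) == side:
                expected = inner
            else:
                expected = total - inner - tree.edge_length(edge)
            assert div == pytest.approx(expected)
            assert divfrac == pytest.approx(div / total)
            assert 0 < frac < 1


def test_robinson_foulds_identical_and_disjoint(quartet):
    assert robinson_foulds(quartet, quartet) == 0
    other = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert robinson_foulds(quartet, other) == 2
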