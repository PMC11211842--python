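"""Per-bipartition feature extraction."""

import numpy as np
import pandas as pd
import pytest

from branchscore.features import (
    FEATURE_COLUMNS,
    compute_features,
    difficulty_proxy,
    neighbor_branches,
)
from branchscore.inference import (
    LikelihoodEngine,
    ParsimonyTreeSet,
    SearchResult,
    ml_search,
    parsimony_tree_sample,
    tree_log_likelihood,
)
from branchscore.phylo import Bipartition, extract_bipartitions, parse_newick
from branchscore.seqsim import (
    MSA,
    SimulationConfig,
    SubstitutionModel,
    sample_model,
    sample_tree,
    simulate_msa,
)
from conftest import random_instance


def _featurize(seed=3, ntaxa=8, nsites=300):
    tree, model, msa = random_instance(seed, ntaxa=ntaxa, nsites=nsites)
    engine = LikelihoodEngine(msa, model)
    res = ml_search(msa, model, n_starts=3, seed=seed, engine=engine)
    ptrees = parsimony_tree_sample(msa, 10, seed + 1, engine=engine)
    df = compute_features(msa, res, ptrees, model, engine=engine, msa_id="m0")
    return tree, model, msa, res, ptrees, df


class TestFeatureTable:
    def test_one_row_per_internal_branch(self):
        tree, model, msa, res, ptrees, df = _featurize()
        assert len(df) == msa.n_seqs - 3
        assert list(df.columns[3:]) == FEATURE_COLUMNS

    def test_alignment_features_constant_within_msa(self):
        _, _, _, _, _, df = _featurize()
        for col in ("n_seqs", "n_sites", "n_unique_sites", "frac_constant_sites",
                    "difficulty"):
            assert df[col].nunique() == 1

    def test_fractions_bounded(self):
        _, _, _, _, _, df = _featurize()
        for col in ("frac_constant_sites", "difficulty", "side_leaf_fraction",
                    "side_divergence_fraction", "parsimony_presence",
                    "subopt_presence"):
            v = df[col].dropna()
            assert ((v >= 0) & (v <= 1)).all()
        assert (df["side_leaf_count"] <= df["n_seqs"] / 2).all()

    def test_full_presence_implies_zero_transfer(self):
        _, _, _, _, _, df = _featurize()
        full = df["parsimony_presence"] == 1.0
        assert (df.loc[full, "parsimony_transfer_mean"] == 0).all()

    def test_equal_lengths_give_unit_ratio(self):
        # trifurcating base so every unrooted edge has length 1
        tree = parse_newick("(A:1,B:1,((C:1,D:1):1,E:1):1);")
        model = SubstitutionModel.jc()
        msa = simulate_msa(tree, model, 200, 1)
        engine = LikelihoodEngine(msa, model)
        ptrees = parsimony_tree_sample(msa, 5, 2, engine=engine)
        ll = tree_log_likelihood(tree, msa, model, engine=engine)
        res = SearchResult(best_tree=tree, best_ll=ll, suboptimal=[])
        df = compute_features(msa, res, ptrees, model, engine=engine)
        assert np.allclose(df["bl_over_tree_mean"], 1.0)
        assert np.allclose(df["bl_over_neighbor_mean"], 1.0)

    def test_suboptimal_features_masked_without_trees(self):
        tree = parse_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.1);")
        model = SubstitutionModel.jc()
        msa = simulate_msa(tree, model, 150, 5)
        engine = LikelihoodEngine(msa, model)
        ptrees = parsimony_tree_sample(msa, 5, 2, engine=engine)
        ll = tree_log_likelihood(tree, msa, model, engine=engine)
        res = SearchResult(best_tree=tree, best_ll=ll, suboptimal=[])
        df = compute_features(msa, res, ptrees, model, engine=engine)
        assert df["subopt_presence"].isna().all()
        assert df["subopt_transfer_mean"].isna().all()

    def test_hand_counted_parsimony_concordance(self):
        """5-taxon instance with hand-built parsimony trees."""
        best = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        model = SubstitutionModel.jc()
        msa = simulate_msa(best, model, 100, 7)
        engine = LikelihoodEngine(msa, model)
        t_same = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        t_alt = parse_newick("(((A:1,C:1):1,B:1):1,(D:1,E:1):1);")
        ptrees = ParsimonyTreeSet(trees=[t_same, t_same, t_alt, t_alt], scores=[0] * 4)
        ll = tree_log_likelihood(best, msa, model, engine=engine)
        res = SearchResult(best_tree=best, best_ll=ll, suboptimal=[])
        df = compute_features(msa, res, ptrees, model, engine=engine)
        df = df.set_index("bipartition_id")
        # split {A,B}: present in t_same only -> presence 1/2
        assert df.loc["A|B", "parsimony_presence"] == pytest.approx(0.5)
        # its transfer distance in t_alt: {A,B} vs {A,C} -> 1, capped p-1=1
        assert df.loc["A|B", "parsimony_transfer_mean"] == pytest.approx(0.5)
        # split {D,E}: present in all four trees
        assert df.loc["D|E", "parsimony_presence"] == pytest.approx(1.0)
        assert df.loc["D|E", "parsimony_transfer_mean"] == pytest.approx(0.0)
        # neighbor analogs of {D,E}: its only internal neighbor branch is
        # the {A,B} split (presence 1/2, mean transfer 1/2)
        assert df.loc["D|E", "nbr_parsimony_presence_mean"] == pytest.approx(0.5)
        assert df.loc["D|E", "nbr_parsimony_presence_min"] == pytest.approx(0.5)
        assert df.loc["D|E", "nbr_parsimony_transfer_mean"] == pytest.approx(0.5)

    def test_no_dependence_on_true_tree(self):
        """Leakage audit: features never see the generating tree."""
        tree, model, msa = random_instance(17, ntaxa=7, nsites=200)
        engine = LikelihoodEngine(msa, model)
        res = ml_search(msa, model, n_starts=3, seed=3, engine=engine)
        ptrees = parsimony_tree_sample(msa, 6, 4, engine=engine)
        a = compute_features(msa, res, ptrees, model, engine=engine)
        b = compute_features(msa, res, ptrees, model, engine=engine)
        pd.testing.assert_frame_equal(a, b)

    def test_difficulty_override(self):
        tree, model, msa, res, ptrees, _ = _featurize(seed=5)
        engine = LikelihoodEngine(msa, model)
        df = compute_features(
            msa, res, ptrees, model, engine=engine, difficulty=0.42
        )
        assert (df["difficulty"] == 0.42).all()


class TestNeighborBranches:
    def test_quartet_has_four_terminal_neighbors(self, quartet):
        bip = extract_bipartitions(quartet)[0]
        lengths = neighbor_branches(quartet, bip)
        assert len(lengths) == 4
        assert sorted(lengths) == pytest.approx([0.1, 0.1, 0.2, 0.2])

    def test_caterpillar_mixed_neighbors(self, caterpillar6):
        for bip in extract_bipartitions(caterpillar6):
            assert len(neighbor_branches(caterpillar6, bip)) == 4


class TestDifficultyProxy:
    def test_clean_signal_scores_low(self):
        tree = parse_newick(
            "((A:0.05,B:0.05):0.4,((C:0.05,D:0.05):0.4,(E:0.05,F:0.05):0.4):0.4);"
        )
        msa = simulate_msa(tree, SubstitutionModel.jc(), 3000, 5)
        ptrees = parsimony_tree_sample(msa, 8, 1)
        assert difficulty_proxy(msa, ptrees) < 0.25

    def test_saturated_data_scores_higher(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)]
        codes = rng.integers(0, 4, size=(8, 300)).astype(np.uint8)
        msa = MSA(labels, codes)
        ptrees = parsimony_tree_sample(msa, 8, 1)
        hard = difficulty_proxy(msa, ptrees)
        tree = parse_newick(
            "((A:0.05,B:0.05):0.4,((C:0.05,D:0.05):0.4,(E:0.05,F:0.05):0.4):0.4);"
        )
        easy_msa = simulate_msa(tree, SubstitutionModel.jc(), 3000, 5)
        easy = difficulty_proxy(easy_msa, parsimony_tree_sample(easy_msa, 8, 1))
        assert hard > easy + 0.2
        assert 0.0 <= hard <= 1.0

    def test_invariant_to_taxon_order(self):
        tree, model, msa = random_instance(23, ntaxa=7, nsites=250)
        ptrees = parsimony_tree_sample(msa, 6, 2)
        base = difficulty_proxy(msa, ptrees)
        # same alignment and trees, rows permuted: exactly invariant
        perm = np.random.default_rng(1).permutation(msa.n_seqs)
        msa2 = MSA([msa.labels[i] for i in perm], msa.codes[perm])
        assert difficulty_proxy(msa2, ptrees) == pytest.approx(base, abs=1e-12)


class TestPermutationInvariance:
    def test_features_stable_under_taxon_relabeling(self):
        """Row order of the MSA must not affect per-split features."""
        tree, model, msa = random_instance(31, ntaxa=7, nsites=250)
        engine = LikelihoodEngine(msa, model)
        res = ml_search(msa, model, n_starts=1, seed=9, engine=engine)
        ptrees = parsimony_tree_sample(msa, 6, 4, engine=engine)
        df = compute_features(msa, res, ptrees, model, engine=engine)

        perm = np.random.default_rng(2).permutation(msa.n_seqs)
        msa2 = MSA([msa.labels[i] for i in perm], msa.codes[perm])
        engine2 = LikelihoodEngine(msa2, model)
        # same topology, reindexed
        from branchscore.phylo import parse_newick as _p

        tree2 = _reorder_tree(res.best_tree, msa2.labels)
        from branchscore.inference import TreeContext, _optimize_all_branches

        res2 = SearchResult(
            best_tree=tree2,
            best_ll=tree_log_likelihood(tree2, msa2, model, engine=engine2),
            suboptimal=[],
        )
        ptrees2 = parsimony_tree_sample(msa2, 6, 4, engine=engine2)
        df2 = compute_features(msa2, res2, ptrees2, model, engine=engine2)
        a = df.set_index("bipartition_id")
        b = df2.set_index("bipartition_id")
        assert set(a.index) == set(b.index)
        for col in ("branch_length", "side_leaf_count", "side_divergence",
                    "total_divergence", "mad_ultrametricity",
                    "neighbor_bl_mean"):
            for bid in a.index:
                assert a.loc[bid, col] == pytest.approx(
                    b.loc[bid, col], rel=1e-6, abs=1e-9
                )


def _reorder_tree(tree, labels):
    from branchscore.cli import _reorder

    return _reorder(tree, labels)
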