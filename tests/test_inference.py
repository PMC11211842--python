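"""Likelihood engine, branch-length optimization, search, parsimony."""

import itertools
import math

import numpy as np
import pytest

from branchscore.inference import (
    LikelihoodEngine,
    TreeContext,
    _optimize_all_branches,
    compress_patterns,
    fitch_score,
    ml_search,
    nj_from_distances,
    nj_tree,
    nni_ll_differences,
    nni_neighbors,
    nni_ll_diffs_all,
    optimize_branch_lengths,
    parsimony_tree_sample,
    tree_log_likelihood,
)
from branchscore.phylo import (
    Bipartition,
    Tree,
    extract_bipartitions,
    parse_newick,
    robinson_foulds,
)
from branchscore.seqsim import (
    MSA,
    SimulationConfig,
    SubstitutionModel,
    sample_model,
    sample_tree,
    simulate_msa,
)
from conftest import random_instance


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_loglik(tree, msa, model):
    """Likelihood by exhaustive enumeration of ancestral states, with
    transition matrices from scipy's matrix exponential (independent of
    the engine's eigendecomposition)."""
    from scipy.linalg import expm

    Q = model.q_matrix()
    crates = model.category_rates()
    fr = model.freqs
    internals = [u for u in tree.postorder() if tree.children[u]]
    total = 0.0
    for site in range(msa.n_sites):
        obs = msa.codes[:, site]
        mix = 0.0
        for c in range(crates.size):
            P = {
                u: expm(Q * crates[c] * tree.blen[u])
                for u in range(tree.n_nodes)
            }
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                pr = fr[amap[tree.root]]
                for u in range(tree.n_nodes):
                    if u == tree.root:
                        continue
                    pu = amap[tree.parent[u]]
                    if tree.children[u]:
                        pr *= P[u][pu, amap[u]]
                    else:
                        k = obs[u]
                        pr *= P[u][pu, k] if k < 4 else 1.0
                s += pr
            mix += s / crates.size
        mix *= 1 - model.pinv
        if model.pinv > 0:
            compat = np.ones(4)
            for u in range(tree.n_leaves):
                if obs[u] < 4:
                    compat *= np.arange(4) == obs[u]
            mix += model.pinv * float((fr * compat).sum())
        total += math.log(mix)
    return total


def brute_force_fitch_column(tree, states):
    """Minimum changes by enumerating internal-node states."""
    internals = [u for u in tree.postorder() if tree.children[u]]
    best = None
    for assign in itertools.product(range(4), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        changes = 0
        for u in range(tree.n_nodes):
            if u == tree.root:
                continue
            pu = amap[tree.parent[u]]
            su = amap[u] if tree.children[u] else states[u]
            if su >= 4:  # ambiguous tip matches anything
                continue
            if su != pu:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestLikelihood:
    def test_two_taxon_closed_forms(self, two_taxon_jc):
        tree, jc = two_taxon_jc
        t = 0.3
        match = MSA(["A", "B"], np.array([[0], [0]], dtype=np.uint8))
        mismatch = MSA(["A", "B"], np.array([[0], [1]], dtype=np.uint8))
        e = math.exp(-4 * t / 3)
        assert tree_log_likelihood(tree, match, jc) == pytest.approx(
            math.log(0.25 * (0.25 + 0.75 * e)), abs=1e-12
        )
        assert tree_log_likelihood(tree, mismatch, jc) == pytest.approx(
            math.log(0.25 * (0.25 - 0.25 * e)), abs=1e-12
        )

    def test_zero_length_single_site(self):
        jc = SubstitutionModel.jc()
        tree = Tree.from_adjacency(["A", "B"], {0: [(1, 0.0)], 1: [(0, 0.0)]})
        msa = MSA(["A", "B"], np.array([[0], [0]], dtype=np.uint8))
        assert tree_log_likelihood(tree, msa, jc) == pytest.approx(math.log(0.25))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        """Pruning equals brute-force state enumeration on <=6 taxa,
        across random GTR+Gamma(+I) models."""
        tree, model, msa = random_instance(seed, nsites=8, pinv=0.1 * (seed % 3))
        ll = tree_log_likelihood(tree, msa, model)
        assert ll == pytest.approx(brute_force_loglik(tree, msa, model), abs=1e-10)

    def test_pattern_compression_is_exact(self):
        tree, model, msa = random_instance(99, ntaxa=6, nsites=400)
        eng_c = LikelihoodEngine(msa, model, compress=True)
        eng_u = LikelihoodEngine(msa, model, compress=False)
        ctx_c = TreeContext(tree, eng_c)
        ctx_u = TreeContext(tree, eng_u)
        ctx_c.compute_down()
        ctx_u.compute_down()
        assert ctx_c.loglik() == pytest.approx(ctx_u.loglik(), abs=1e-12)


class TestBranchOptimization:
    def test_two_taxon_jc_closed_form(self):
        jc = SubstitutionModel.jc()
        tree = Tree.from_adjacency(["A", "B"], {0: [(1, 0.4)], 1: [(0, 0.4)]})
        msa = simulate_msa(tree, jc, 5000, 11)
        phat = (msa.codes[0] != msa.codes[1]).mean()
        expect = -0.75 * math.log(1 - 4 * phat / 3)
        start = tree.copy()
        start.blen[:] = 0.0
        start.blen[1] = 0.05
        out = optimize_branch_lengths(start, msa, jc, scope="all")
        assert out.blen[1] + out.blen[0] == pytest.approx(expect, abs=1e-4)

    def test_ascent_and_idempotence(self):
        tree, model, msa = random_instance(5, ntaxa=8, nsites=300)
        ll0 = tree_log_likelihood(tree, msa, model)
        opt = optimize_branch_lengths(tree, msa, model, scope="all")
        ll1 = tree_log_likelihood(opt, msa, model)
        assert ll1 >= ll0 - 1e-9
        again = optimize_branch_lengths(opt, msa, model, scope="all")
        ll2 = tree_log_likelihood(again, msa, model)
        assert abs(ll2 - ll1) < 1e-3

    def test_local_scope_touches_only_five_branches(self):
        tree, model, msa = random_instance(8, ntaxa=8, nsites=200)
        bip = extract_bipartitions(tree)[0]
        out = optimize_branch_lengths(tree, msa, model, scope=bip)
        changed = np.flatnonzero(~np.isclose(out.blen, tree.blen))
        assert 1 <= changed.size <= 5


class TestNeighborJoining:
    def test_additive_distances_recover_topology(self):
        tree = sample_tree(10, SimulationConfig(), 17)
        # exact path distances from the tree itself
        from branchscore.phylo import Tree as _T

        n = tree.n_leaves
        from branchscore.phylo import _node_leaf_distances

        D = _node_leaf_distances(tree)[:n, :]
        nj = nj_from_distances(D, list(tree.labels))
        assert robinson_foulds(nj, tree) == 0

    def test_quartet_from_clocklike_distances(self):
        labels = ["A", "B", "C", "D"]
        # ((A,B),(C,D)) with internal branch 2
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        nj = nj_from_distances(D, labels)
        bip = Bipartition({"A", "B"}, set(labels))
        assert bip in set(extract_bipartitions(nj))

    def test_identical_sequences_give_zero_lengths(self):
        msa = MSA(["A", "B", "C", "D"], np.zeros((4, 50), dtype=np.uint8))
        nj = nj_tree(msa)
        assert nj.total_divergence() == pytest.approx(0.0)
        assert nj.is_binary()


class TestNNI:
    def test_quartet_neighbors(self, quartet):
        bip = extract_bipartitions(quartet)[0]
        n1, n2 = nni_neighbors(quartet, bip)
        splits = {extract_bipartitions(t)[0].id_string() for t in (n1, n2)}
        taxa = set(quartet.labels)
        expected = {
            Bipartition({"A", "C"}, taxa).id_string(),
            Bipartition({"A", "D"}, taxa).id_string(),
        }
        assert splits == expected

    def test_involution(self):
        tree = sample_tree(8, SimulationConfig(), 4)
        bip = extract_bipartitions(tree)[2]
        n1, _ = nni_neighbors(tree, bip)
        # the same central branch exists in the neighbor; swapping back
        # must recover the original split set
        back_splits = [
            set(extract_bipartitions(t)) for t in nni_neighbors(n1, _central(n1, tree))
        ]
        assert set(extract_bipartitions(tree)) in back_splits

    def test_total_distinct_neighbors(self):
        tree = sample_tree(9, SimulationConfig(), 6)
        seen = set()
        for bip in extract_bipartitions(tree):
            for t in nni_neighbors(tree, bip):
                seen.add(frozenset(extract_bipartitions(t)))
        assert len(seen) == 2 * (tree.n_leaves - 3)


def _central(neighbor, original):
    """The bipartition of `neighbor` absent from `original` (the swapped
    branch)."""
    diff = set(extract_bipartitions(neighbor)) - set(extract_bipartitions(original))
    return next(iter(diff))


class TestFitch:
    def test_constant_column_zero(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        msa = MSA(list("ABCD"), np.zeros((4, 3), dtype=np.uint8))
        assert fitch_score(tree, msa) == 0

    def test_simple_column(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        msa = MSA(list("ABCD"), np.array([[0], [0], [2], [2]], dtype=np.uint8))
        assert fitch_score(tree, msa) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimization(self, seed):
        rng = np.random.default_rng(seed)
        tree = sample_tree(int(rng.integers(4, 7)), SimulationConfig(),
                           int(rng.integers(2**31)))
        ncols = 10
        codes = rng.integers(0, 4, size=(tree.n_leaves, ncols)).astype(np.uint8)
        # sprinkle ambiguity
        codes[rng.random(codes.shape) < 0.1] = 4
        msa = MSA(list(tree.labels), codes)
        expected = sum(
            brute_force_fitch_column(tree, codes[:, j]) for j in range(ncols)
        )
        assert fitch_score(tree, msa) == expected


class TestParsimonySample:
    def test_counts_and_validity(self):
        _, model, msa = random_instance(3, ntaxa=8, nsites=200)
        ps = parsimony_tree_sample(msa, 10, 7)
        assert len(ps.trees) == 10
        for t, s in zip(ps.trees, ps.scores):
            assert t.is_binary()
            assert sorted(t.labels) == sorted(msa.labels)
            assert s == fitch_score(t, msa)

    def test_deterministic(self):
        _, model, msa = random_instance(4, ntaxa=7, nsites=150)
        a = parsimony_tree_sample(msa, 5, 3)
        b = parsimony_tree_sample(msa, 5, 3)
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_recovers_strong_signal(self):
        # long internal branches, many sites: every parsimony tree should
        # contain the true splits
        tree = parse_newick(
            "((A:0.05,B:0.05):0.4,((C:0.05,D:0.05):0.4,(E:0.05,F:0.05):0.4):0.4);"
        )
        msa = simulate_msa(tree, SubstitutionModel.jc(), 3000, 5)
        ps = parsimony_tree_sample(msa, 8, 1)
        true_splits = set(extract_bipartitions(tree))
        for t in ps.trees:
            assert true_splits <= set(extract_bipartitions(t))


class TestSearch:
    def test_recovers_easy_instance(self):
        tree = parse_newick(
            "((A:0.05,B:0.05):0.3,((C:0.05,D:0.05):0.3,(E:0.05,F:0.05):0.3):0.3);"
        )
        model = SubstitutionModel.jc()
        msa = simulate_msa(tree, model, 4000, 9)
        res = ml_search(msa, model, n_starts=3, seed=2)
        assert robinson_foulds(res.best_tree, tree) == 0

    def test_best_dominates_suboptimal(self):
        tree, model, msa = random_instance(11, ntaxa=10, nsites=400)
        res = ml_search(msa, model, n_starts=3, seed=5)
        assert len(res.suboptimal) == 2
        for _, ll in res.suboptimal:
            assert res.best_ll >= ll - 1e-6

    def test_deterministic(self):
        tree, model, msa = random_instance(12, ntaxa=9, nsites=300)
        a = ml_search(msa, model, n_starts=3, seed=8)
        b = ml_search(msa, model, n_starts=3, seed=8)
        assert a.best_tree.to_newick() == b.best_tree.to_newick()
        assert a.best_ll == pytest.approx(b.best_ll, abs=1e-9)


class TestNNIDifferences:
    def test_strong_branch_has_positive_min_diff(self):
        tree = parse_newick(
            "((A:0.05,B:0.05):0.4,(C:0.05,D:0.05):0.4);"
        )
        model = SubstitutionModel.jc()
        msa = simulate_msa(tree, model, 3000, 13)
        res = ml_search(msa, model, n_starts=3, seed=1)
        bip = extract_bipartitions(res.best_tree)[0]
        dmin, dmax = nni_ll_differences(res, bip, msa, model)
        assert dmin > 0
        assert dmin <= dmax

    def test_plateau_branch_has_near_zero_diffs(self):
        # a star-like instance: zero internal branch
        tree = parse_newick("((A:0.1,B:0.1):0.0,(C:0.1,D:0.1):0.0);")
        model = SubstitutionModel.jc()
        msa = simulate_msa(tree, model, 500, 3)
        engine = LikelihoodEngine(msa, model)
        opt = optimize_branch_lengths(tree, msa, model, scope="all", engine=engine)
        diffs = nni_ll_diffs_all(opt, engine)
        dmin, dmax = list(diffs.values())[0]
        assert abs(dmin) < 3.0 and abs(dmax) < 3.0

    def test_min_le_max_everywhere(self):
        tree, model, msa = random_instance(21, ntaxa=9, nsites=250)
        res = ml_search(msa, model, n_starts=3, seed=4)
        engine = LikelihoodEngine(msa, model)
        for dmin, dmax in nni_ll_diffs_all(
            res.best_tree, engine, best_ll=res.best_ll
        ).values():
            assert dmin <= dmax + 1e-9
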