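"""Likelihood engine, tree search, and parsimony machinery.

The maximum-likelihood tree is obtained by an internal multi-start search:
a neighbor-joining start plus randomized-addition parsimony starts, each
improved by greedy NNI hill-climbing.  Candidate NNIs are scored with
aLRT-style local optimization (the central branch and its four neighbors,
with the rest of the tree's conditional likelihoods held fixed), and full
branch-length optimization is run on accepted moves.  Site patterns are
compressed once per alignment; likelihoods use Felsenstein pruning under
GTR+Gamma(+I) with eigendecomposition in the frequency-symmetrized basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .phylo import Bipartition, Tree
from .seqsim import MSA, SubstitutionModel

MIN_BLEN = K.MIN_BLEN
MAX_BLEN = K.MAX_BLEN
JC_MAX_DIST = 5.0


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pattern compression
# ---------------------------------------------------------------------------


def compress_patterns(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their weights."""
    cols = np.ascontiguousarray(codes.T)
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return np.ascontiguousarray(uniq.T), counts.astype(np.float64)


# ---------------------------------------------------------------------------
# engine + per-tree context
# ---------------------------------------------------------------------------


class LikelihoodEngine:
    """Per-alignment state shared by all likelihood computations."""

    def __init__(self, msa: MSA, model: SubstitutionModel, compress: bool = True):
        self.msa = msa
        self.model = model
        if compress:
            self.patterns, self.weights = compress_patterns(msa.codes)
        else:
            self.patterns = np.ascontiguousarray(msa.codes)
            self.weights = np.ones(msa.n_sites)
        V, Vinv, lam = model.eigensystem()
        self.V = np.ascontiguousarray(V)
        self.Vinv = np.ascontiguousarray(Vinv)
        self.lam = np.ascontiguousarray(lam)
        self.crates = np.ascontiguousarray(model.category_rates())
        self.freqs = np.ascontiguousarray(model.freqs)
        self.pinv = float(model.pinv)
        self.ncat = self.crates.size
        # invariant-class site likelihoods
        P = self.patterns.shape[1]
        compat = np.ones((P, 4), dtype=bool)
        for row in self.patterns:
            obs = row[:, None] == np.arange(4)[None, :]
            amb = (row >= 4)[:, None]
            compat &= obs | amb
        self.linv = np.ascontiguousarray((compat * self.freqs).sum(axis=1))
        # Fitch bitmask tip sets
        tips = self.patterns
        self.tipsets = np.where(tips < 4, (1 << tips).astype(np.uint8), np.uint8(15))
        self.tipsets = np.ascontiguousarray(self.tipsets)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]


class TreeContext:
    """CLV workspace bound to one (tree, engine) pair.

    Rebuild (cheap) after any topology change; branch lengths are read
    from ``tree.blen`` at computation time.
    """

    def __init__(self, tree: Tree, engine: LikelihoodEngine):
        self.engine = engine
        n = tree.n_leaves
        N = tree.n_nodes
        self.nleaves = n
        P = engine.n_patterns
        C = engine.ncat
        self.clv = np.zeros((N, P, C, 4))
        self.lsc = np.zeros((N, P))
        self.uvec = np.zeros((N, P, C, 4))
        self.ulsc = np.zeros((N, P))
        # leaf rows of clv = tip indicator messages (state 4 = all ones)
        tips = engine.patterns
        for leaf in range(n):
            row = tips[leaf]
            ind = np.zeros((P, 4))
            known = row < 4
            ind[np.arange(P)[known], row[known]] = 1.0
            ind[~known] = 1.0
            self.clv[leaf] = ind[:, None, :]
        self._zero = np.zeros(P)
        self.qws = np.empty((6, P, C, 4))
        self.qls = np.empty((3, P))
        self.rebind(tree)

    def rebind(self, tree: Tree) -> None:
        """Point the workspace at a (possibly rearranged) tree on the same
        leaf set; the large CLV buffers are reused."""
        if list(tree.labels) != list(self.engine.msa.labels):
            raise InferenceError("tree and alignment leaf sets differ")
        if not tree.is_binary():
            raise InferenceError("likelihood context requires a binary tree")
        if tree.n_nodes != self.clv.shape[0]:
            raise InferenceError("node count changed; build a fresh context")
        self.tree = tree
        N = tree.n_nodes
        self.child1 = np.full(N, -1, dtype=np.int32)
        self.child2 = np.full(N, -1, dtype=np.int32)
        for u in range(N):
            ch = tree.children[u]
            if ch:
                self.child1[u] = ch[0]
                self.child2[u] = ch[1]
        self.parent = tree.parent.astype(np.int32)
        post = tree.postorder()
        self.post_internal = np.array(
            [u for u in post if tree.children[u]], dtype=np.int32
        )
        self.pre_edges = np.array(
            [u for u in reversed(post) if u != tree.root and u != 0],
            dtype=np.int32,
        )

    # -- computations -------------------------------------------------------

    def blen(self) -> np.ndarray:
        return self.tree.blen

    def compute_down(self) -> None:
        e = self.engine
        K.down_pass(
            self.post_internal,
            self.child1,
            self.child2,
            self.tree.blen,
            e.patterns,
            self.nleaves,
            e.V,
            e.Vinv,
            e.lam,
            e.crates,
            self.clv,
            self.lsc,
        )

    def compute_up(self) -> None:
        e = self.engine
        K.up_pass(
            self.pre_edges,
            self.parent,
            self.child1,
            self.child2,
            self.tree.blen,
            e.patterns,
            self.nleaves,
            e.freqs,
            self.tree.root,
            e.V,
            e.Vinv,
            e.lam,
            e.crates,
            self.clv,
            self.lsc,
            self.uvec,
            self.ulsc,
        )

    def loglik(self) -> float:
        e = self.engine
        r = self.tree.root
        return float(
            K.root_loglik(
                self.clv[r], self.lsc[r], e.freqs, e.weights, e.pinv, e.linv
            )
        )

    def refresh_node(self, u: int) -> None:
        e = self.engine
        K.down_pass(
            np.array([u], dtype=np.int32),
            self.child1,
            self.child2,
            self.tree.blen,
            e.patterns,
            self.nleaves,
            e.V,
            e.Vinv,
            e.lam,
            e.crates,
            self.clv,
            self.lsc,
        )

    def down_msg(self, u: int) -> Tuple[np.ndarray, np.ndarray]:
        """(message, logscale) of node u's subtree (leaf rows prefilled)."""
        if u < self.nleaves:
            return self.clv[u], np.zeros(self.engine.n_patterns)
        return self.clv[u], self.lsc[u]

    def quartet_parts(self, x: int):
        """Messages and lengths of the local system around internal edge x:
        (A, B) below x, C the sibling, U the time-reversed rest at
        parent(x); t = [tA, tB, tC, tU, t_center]."""
        tree = self.tree
        p = int(tree.parent[x])
        c1, c2 = tree.children[x]
        sib = [c for c in tree.children[p] if c != x][0]
        A, lsA = self.down_msg(c1)
        B, lsB = self.down_msg(c2)
        Cm, lsC = self.down_msg(sib)
        U = self.uvec[p]
        lsU = self.ulsc[p]
        t = np.array(
            [tree.blen[c1], tree.blen[c2], tree.blen[sib], tree.blen[p], tree.blen[x]]
        )
        return (A, lsA, B, lsB, Cm, lsC, U, lsU, t, (c1, c2, sib, p))


# ---------------------------------------------------------------------------
# log-likelihood and branch-length optimization
# ---------------------------------------------------------------------------


def tree_log_likelihood(
    tree: Tree,
    msa: MSA,
    model: SubstitutionModel,
    engine: Optional[LikelihoodEngine] = None,
) -> float:
    """Felsenstein-pruning log-likelihood (Gamma/I mixture, compressed
    site patterns)."""
    engine = engine or LikelihoodEngine(msa, model)
    ctx = TreeContext(tree, engine)
    ctx.compute_down()
    return ctx.loglik()


def _optimize_all_branches(
    ctx: TreeContext,
    max_sweeps: int = 5,
    ll_tol: float = 1e-4,
    xtol: float = 1e-6,
) -> float:
    """Coordinate-wise branch-length optimization by depth-first sweeps.

    Each 1-D optimization uses exact conditional likelihoods for the
    current parameter values (down-CLVs are refreshed on the way back up),
    so the log-likelihood is non-decreasing across every accepted step.
    """
    e = ctx.engine
    tree = ctx.tree

    ctx.compute_down()
    ll_prev = ctx.loglik()

    root = tree.root
    v = [c for c in tree.children[root] if c != 0][0]
    # prior-laden up-message for the start edge: pi o (leaf-0 tip at t=0)
    U0 = ctx.clv[0] * e.freqs[None, None, :]

    for sweep in range(max_sweeps):
        ctx.uvec[v] = U0
        ctx.ulsc[v] = 0.0
        K.sweep_branch_lengths(
            v,
            ctx.parent,
            ctx.child1,
            ctx.child2,
            tree.blen,
            ctx.clv,
            ctx.lsc,
            ctx.uvec,
            ctx.ulsc,
            e.V,
            e.Vinv,
            e.lam,
            e.crates,
            e.weights,
            e.pinv,
            e.linv,
            xtol,
        )
        ctx.refresh_node(root)
        ll = ctx.loglik()
        if ll - ll_prev < ll_tol:
            ll_prev = max(ll, ll_prev)
            break
        ll_prev = ll
    return ll_prev


def optimize_branch_lengths(
    tree: Tree,
    msa: MSA,
    model: SubstitutionModel,
    scope: str | Bipartition = "all",
    engine: Optional[LikelihoodEngine] = None,
    max_sweeps: int = 5,
) -> Tree:
    """Optimize branch lengths; ``scope`` is "all" or a Bipartition for
    aLRT-style local-5 optimization (that branch plus its <=4 neighbors).
    Returns a new tree."""
    engine = engine or LikelihoodEngine(msa, model)
    out = tree.copy()
    ctx = TreeContext(out, engine)
    if scope == "all":
        _optimize_all_branches(ctx, max_sweeps=max_sweeps)
        return out
    if not isinstance(scope, Bipartition):
        raise InferenceError("scope must be 'all' or a Bipartition")
    x = _find_edge(out, scope)
    ctx.compute_down()
    ctx.compute_up()
    e = engine
    A, lsA, B, lsB, Cm, lsC, U, lsU, t, nodes = ctx.quartet_parts(x)
    K.quartet_optimize(
        A, lsA, B, lsB, Cm, lsC, U, lsU, t,
        e.V, e.Vinv, e.lam, e.crates, e.weights, e.pinv, e.linv, 3, 1e-6,
        ctx.qws, ctx.qls,
    )
    c1, c2, sib, p = nodes
    out.blen[c1], out.blen[c2], out.blen[sib], out.blen[p], out.blen[x] = t
    return out


def _find_edge(tree: Tree, bip: Bipartition) -> int:
    masks = tree.subtree_masks()
    index = {lb: i for i, lb in enumerate(tree.labels)}
    target = np.zeros(tree.n_leaves, dtype=bool)
    for lb in bip.side:
        target[index[lb]] = True
    for x in tree.internal_edge_nodes():
        if np.array_equal(masks[x], target) or np.array_equal(masks[x], ~target):
            return x
    raise InferenceError("bipartition is not an internal branch of the tree")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(msa: MSA, model: Optional[SubstitutionModel] = None) -> Tree:
    """Neighbor joining on Jukes-Cantor distances; negative branch
    lengths clamped to 0, saturated pairs capped at a maximum distance."""
    n = msa.n_seqs
    if n < 4:
        raise InferenceError("neighbor joining needs at least 4 sequences")
    patterns, w = compress_patterns(msa.codes)
    pd = K.pdist_matrix(np.ascontiguousarray(patterns), w)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = -0.75 * np.log1p(-(4.0 / 3.0) * pd)
    D[~np.isfinite(D)] = JC_MAX_DIST
    D = np.minimum(D, JC_MAX_DIST)
    return nj_from_distances(D, list(msa.labels))


def nj_from_distances(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Classic neighbor joining on a symmetric distance matrix."""
    n = len(labels)
    if n < 4:
        raise InferenceError("neighbor joining needs at least 4 taxa")
    ids = list(range(n))
    adj: Dict[int, List[Tuple[int, float]]] = {i: [] for i in range(n)}
    next_id = n
    active = ids[:]
    Dm = D.copy()
    idx = {i: k for k, i in enumerate(active)}

    def dist(a, b):
        return Dm[idx[a], idx[b]]

    while len(active) > 3:
        r = len(active)
        sub = Dm[np.ix_([idx[a] for a in active], [idx[a] for a in active])]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        u = next_id
        next_id += 1
        adj[u] = []
        for node, ln in ((a, vi), (b, vj)):
            adj[u].append((node, ln))
            adj[node].append((u, ln))
        newd = 0.5 * (sub[i, :] + sub[j, :] - dij)
        # rebuild distance bookkeeping
        keep = [k for k in range(r) if k not in (i, j)]
        new_active = [active[k] for k in keep] + [u]
        m = len(new_active)
        Dn = np.zeros((m, m))
        Dn[: m - 1, : m - 1] = sub[np.ix_(keep, keep)]
        Dn[m - 1, : m - 1] = newd[keep]
        Dn[: m - 1, m - 1] = newd[keep]
        Dm = Dn
        active = new_active
        idx = {node: k for k, node in enumerate(active)}

    a, b, c = active
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    u = next_id
    adj[u] = []
    for node, ln in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        ln = max(ln, 0.0)
        adj[u].append((node, ln))
        adj[node].append((u, ln))
    return Tree.from_adjacency(list(labels), adj)


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------


def _nni_apply(tree: Tree, x: int, which: int) -> Tree:
    """Swap child ``which`` of internal edge node x with x's sibling."""
    out = tree.copy()
    p = int(out.parent[x])
    c = out.children[x][which]
    sib_pos = 0 if out.children[p][0] != x else 1
    sib = out.children[p][sib_pos]
    out.children[x][which] = sib
    out.parent[sib] = x
    out.children[p][sib_pos] = c
    out.parent[c] = p
    out.invalidate()
    return out


def nni_neighbors(tree: Tree, branch: Bipartition) -> Tuple[Tree, Tree]:
    """The two alternative resolutions of the quartet around an internal
    branch; applying the same NNI twice restores the original topology."""
    x = _find_edge(tree, branch)
    return _nni_apply(tree, x, 1), _nni_apply(tree, x, 0)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def _tipsets_for(msa: MSA) -> Tuple[np.ndarray, np.ndarray]:
    patterns, w = compress_patterns(msa.codes)
    tipsets = np.where(
        patterns < 4, (1 << patterns.astype(np.uint8)), np.uint8(15)
    ).astype(np.uint8)
    return np.ascontiguousarray(tipsets), w


def fitch_score(tree: Tree, msa: MSA, engine: Optional[LikelihoodEngine] = None) -> int:
    """Minimum number of state changes (Fitch small parsimony), gaps and
    ambiguities treated as the full state set."""
    if list(tree.labels) != list(msa.labels):
        raise InferenceError("tree and alignment leaf sets differ")
    if engine is not None:
        tipsets, w = engine.tipsets, engine.weights
    else:
        tipsets, w = _tipsets_for(msa)
    N = tree.n_nodes
    child1 = np.full(N, -1, dtype=np.int32)
    child2 = np.full(N, -1, dtype=np.int32)
    for u in range(N):
        if tree.children[u]:
            child1[u] = tree.children[u][0]
            child2[u] = tree.children[u][1]
    order = np.array(
        [u for u in tree.postorder() if tree.children[u]], dtype=np.int32
    )
    return int(round(K.fitch_score(order, child1, child2, tree.n_leaves, tipsets, w)))


@dataclass
class ParsimonyTreeSet:
    trees: List[Tree]
    scores: List[int]


def parsimony_tree_sample(
    msa: MSA,
    n_trees: int,
    seed: int,
    engine: Optional[LikelihoodEngine] = None,
) -> ParsimonyTreeSet:
    """Randomized stepwise-addition parsimony trees on the original
    alignment: each taxon is inserted at a Fitch-optimal branch, ties
    broken uniformly at random."""
    n = msa.n_seqs
    if n < 4:
        raise InferenceError("need at least 4 taxa")
    if engine is not None:
        tipsets, w = engine.tipsets, engine.weights
    else:
        tipsets, w = _tipsets_for(msa)
    rng = np.random.default_rng(seed)
    # insertion decisions only need patterns whose attachment cost can
    # vary across edges; fully constant patterns shift every cost equally
    if engine is not None:
        patterns = engine.patterns
    else:
        patterns = compress_patterns(msa.codes)[0]
    present = np.zeros((patterns.shape[1], 4), dtype=bool)
    for s in range(4):
        present[:, s] = (patterns == s).any(axis=0)
    var = present.sum(axis=1) >= 2
    if not var.any():
        var[0] = True
    tipsets_v = np.ascontiguousarray(tipsets[:, var])
    w_v = np.ascontiguousarray(w[var])
    trees, scores = [], []
    for _ in range(n_trees):
        tree = _stepwise_tree(msa, tipsets_v, w_v, rng)
        trees.append(tree)
        scores.append(fitch_score(tree, msa, engine=engine))
    return ParsimonyTreeSet(trees=trees, scores=scores)


def _stepwise_tree(
    msa: MSA, tipsets: np.ndarray, w: np.ndarray, rng: np.random.Generator
) -> Tree:
    n = msa.n_seqs
    P = tipsets.shape[1]
    Nmax = 2 * n - 1
    root = Nmax - 1
    parent = np.empty(Nmax, dtype=np.int32)
    child1 = np.empty(Nmax, dtype=np.int32)
    child2 = np.empty(Nmax, dtype=np.int32)
    dsets = np.zeros((Nmax, P), dtype=np.uint8)
    usets = np.zeros((Nmax, P), dtype=np.uint8)
    perm = rng.permutation(n).astype(np.int32)
    rand_u = rng.random(n)
    K.stepwise_build(
        perm, np.ascontiguousarray(tipsets), w, rand_u,
        parent, child1, child2, dsets, usets,
    )
    l0 = int(perm[0])
    # convert to adjacency (merge the two root edges)
    adj: Dict[int, List[Tuple[int, float]]] = {}
    for u in range(Nmax):
        if parent[u] >= 0 and parent[u] != root:
            adj.setdefault(u, []).append((int(parent[u]), 0.1))
            adj.setdefault(int(parent[u]), []).append((u, 0.1))
    rc = child1[root] if child1[root] != l0 else child2[root]
    adj.setdefault(l0, []).append((int(rc), 0.1))
    adj.setdefault(int(rc), []).append((l0, 0.1))
    return Tree.from_adjacency(list(msa.labels), adj)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    best_tree: Tree
    best_ll: float
    suboptimal: List[Tuple[Tree, float]]
    trace: dict = field(default_factory=dict)


def _apply_move(tree: Tree, move) -> Tree:
    x, which, t5, nodes = move
    c1, c2, sib, p = nodes
    tree = _nni_apply(tree, x, which)
    # optimized local lengths follow their subtrees
    kept = c1 if which == 1 else c2
    moved = c2 if which == 1 else c1
    tree.blen[kept] = t5[0]
    tree.blen[sib] = t5[1]
    tree.blen[moved] = t5[2]
    tree.blen[p] = t5[3]
    tree.blen[x] = t5[4]
    return tree


def _hill_climb(
    tree: Tree,
    engine: LikelihoodEngine,
    accept_tol: float = 0.1,
    max_rounds: int = 25,
    init_sweeps: int = 2,
) -> Tuple[Tree, float, int]:
    """NNI hill-climbing with aLRT-style local-5 candidate scoring.

    Each round scores both NNIs around every internal branch against the
    current tree (central-branch prefilter, then local-5 optimization for
    near-competitive swaps) and applies all improving, non-conflicting
    moves at once, best first; a full branch-length sweep follows.  If a
    simultaneous batch ever fails to improve the likelihood it is rolled
    back and only the single best move is applied, so accepted
    log-likelihoods are non-decreasing.
    """
    e = engine
    tree = tree.copy()
    ctx = TreeContext(tree, engine)
    ll = _optimize_all_branches(ctx, max_sweeps=init_sweeps, ll_tol=0.05)
    moves = 0
    dirty = None  # None = scan every edge; else only edges near recent moves
    for _round in range(max_rounds):
        ctx.rebind(tree)
        ctx.compute_down()
        ctx.compute_up()
        ll = ctx.loglik()
        internal = tree.internal_edge_nodes()
        if dirty is None:
            scan = internal
        else:
            scan = [
                x
                for x in internal
                if (
                    {x, int(tree.parent[x]), *tree.children[x],
                     *tree.children[int(tree.parent[x])]}
                    & dirty
                )
            ]
        improving = []
        if scan:
            edges = np.array(scan, dtype=np.int32)
            E = edges.size
            gains = np.empty(E)
            whichs = np.empty(E, dtype=np.int64)
            t5out = np.empty((E, 5))
            K.scan_nnis(
                edges, ctx.parent, ctx.child1, ctx.child2, tree.blen,
                ctx.clv, ctx.lsc, ctx.uvec, ctx.ulsc,
                e.V, e.Vinv, e.lam, e.crates, e.weights, e.pinv, e.linv,
                ll, 0.25, 1, ctx.qws, ctx.qls, gains, whichs, t5out,
            )
            for ei in range(E):
                if gains[ei] > accept_tol:
                    x = int(edges[ei])
                    p = int(tree.parent[x])
                    c1, c2 = tree.children[x]
                    sib = [c for c in tree.children[p] if c != x][0]
                    improving.append(
                        (
                            float(gains[ei]),
                            (x, int(whichs[ei]), t5out[ei].copy(), (c1, c2, sib, p)),
                        )
                    )
        if not improving:
            if dirty is None:
                break
            dirty = None  # nothing locally; verify with one full rescan
            continue
        improving.sort(key=lambda g: -g[0])
        saved = tree.copy()
        used: set = set()
        applied = 0
        for gain, move in improving:
            x, which, t5, nodes = move
            footprint = {x, *nodes}
            if footprint & used:
                continue
            tree = _apply_move(tree, move)
            used |= footprint
            applied += 1
        ctx.rebind(tree)
        new_ll = _optimize_all_branches(ctx, max_sweeps=1)
        if new_ll < ll and applied > 1:
            # simultaneous batch overshot: apply only the best move
            tree = _apply_move(saved, improving[0][1])
            ctx.rebind(tree)
            new_ll = _optimize_all_branches(ctx, max_sweeps=1)
            applied = 1
        if new_ll < ll:
            tree = saved
            ctx.rebind(tree)
            break
        ll = new_ll
        moves += applied
        # widen the rescan region one hop beyond the applied footprints
        dirty = set(used)
        for u in list(used):
            dirty.update(tree.children[u])
            if tree.parent[u] >= 0:
                dirty.add(int(tree.parent[u]))
    ctx.rebind(tree)
    ll = _optimize_all_branches(ctx, max_sweeps=4)
    return tree, ll, moves


def ml_search(
    msa: MSA,
    model: SubstitutionModel,
    n_starts: int = 3,
    seed: int = 0,
    engine: Optional[LikelihoodEngine] = None,
) -> SearchResult:
    """Multi-start ML tree search: NJ start plus randomized-addition
    parsimony starts, each refined by NNI hill-climbing.  Non-best final
    trees are retained as the suboptimal set.

    Hill-climbing runs under a 2-category Gamma approximation of the fit
    model (substantially cheaper, near-identical topologies); the final
    trees are rescored, and the best tree's branch lengths reoptimized,
    under the full model.
    """
    if msa.n_seqs < 4:
        raise InferenceError("need at least 4 taxa")
    engine = engine or LikelihoodEngine(msa, model)
    if model.alpha is not None and model.ncat > 2:
        search_model = SubstitutionModel(
            rates=model.rates, freqs=model.freqs,
            alpha=model.alpha, pinv=model.pinv, ncat=2,
        )
        search_engine = LikelihoodEngine(msa, search_model)
    else:
        search_engine = engine
    rng = np.random.default_rng(seed)
    starts: List[Tree] = [nj_tree(msa, model)]
    if n_starts > 1:
        pset = parsimony_tree_sample(
            msa, n_starts - 1, int(rng.integers(2**31 - 1)), engine=engine
        )
        for t in pset.trees:
            t.blen[:] = 0.1
            t.blen[t.root] = 0.0
            t.blen[0] = 0.0
            starts.append(t)
    finals: List[Tuple[Tree, float, int]] = []
    for si, st in enumerate(starts):
        st.blen[:] = np.clip(st.blen, MIN_BLEN, MAX_BLEN)
        st.blen[st.root] = 0.0
        st.blen[0] = 0.0
        # NJ starts carry distance-based lengths; parsimony starts begin
        # from flat lengths and need an extra initial sweep
        finals.append(
            _hill_climb(st, search_engine, init_sweeps=1 if si == 0 else 2)
        )
    # rescore under the full model
    full_lls: List[float] = []
    ctx: Optional[TreeContext] = None
    for t_, _, _ in finals:
        if ctx is None:
            ctx = TreeContext(t_, engine)
        else:
            ctx.rebind(t_)
        ctx.compute_down()
        full_lls.append(ctx.loglik())
    best_i = int(np.argmax(full_lls))
    best_tree = finals[best_i][0]
    ctx.rebind(best_tree)
    best_ll = _optimize_all_branches(ctx, max_sweeps=3)
    subopt = [
        (f[0], full_lls[i]) for i, f in enumerate(finals) if i != best_i
    ]
    return SearchResult(
        best_tree=best_tree,
        best_ll=best_ll,
        suboptimal=subopt,
        trace={"n_starts": len(starts), "moves": [f[2] for f in finals]},
    )


# ---------------------------------------------------------------------------
# NNI log-likelihood differences
# ---------------------------------------------------------------------------


def nni_ll_diffs_all(
    tree: Tree, engine: LikelihoodEngine, best_ll: Optional[float] = None
) -> Dict[int, Tuple[float, float]]:
    """(min, max) log-likelihood difference between the tree and its two
    locally re-optimized NNI neighbors, for every internal edge node."""
    e = engine
    ctx = TreeContext(tree, engine)
    ctx.compute_down()
    ctx.compute_up()
    ll = ctx.loglik() if best_ll is None else best_ll
    internal = tree.internal_edge_nodes()
    if not internal:
        return {}
    edges = np.array(internal, dtype=np.int32)
    E = edges.size
    gains = np.empty(E)
    whichs = np.empty(E, dtype=np.int64)
    lls = np.empty((E, 5))
    K.scan_nnis(
        edges, ctx.parent, ctx.child1, ctx.child2, tree.blen,
        ctx.clv, ctx.lsc, ctx.uvec, ctx.ulsc,
        e.V, e.Vinv, e.lam, e.crates, e.weights, e.pinv, e.linv,
        ll, 0.0, -2, ctx.qws, ctx.qls, gains, whichs, lls,
    )
    out: Dict[int, Tuple[float, float]] = {}
    for ei, x in enumerate(internal):
        d1 = ll - lls[ei, 0]
        d2 = ll - lls[ei, 1]
        out[x] = (min(d1, d2), max(d1, d2))
    return out


def nni_ll_differences(
    result: SearchResult,
    branch: Bipartition,
    msa: MSA,
    model: SubstitutionModel,
    engine: Optional[LikelihoodEngine] = None,
) -> Tuple[float, float]:
    engine = engine or LikelihoodEngine(msa, model)
    x = _find_edge(result.best_tree, branch)
    diffs = nni_ll_diffs_all(result.best_tree, engine, best_ll=result.best_ll)
    return diffs[x]
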