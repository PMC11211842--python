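"""Unrooted phylogenies, bipartitions, and tree-level statistics.

Trees are stored in a rooted array representation: a virtual root sits on
the pendant edge of leaf 0, so every node except the root and leaf 0
corresponds to exactly one edge of the underlying unrooted tree (the edge
toward its parent).  This makes postorder/preorder dynamic programs over
edges trivial to vectorize and is the layout consumed by the likelihood and
parsimony kernels.

Branch lengths are in expected substitutions per site.  For n >= 3 the
length of leaf 0's pendant edge is carried by the root's other child and
``blen[0]`` is zero; a 2-leaf tree keeps both halves of its single edge so
that the stored "root split" survives round trips.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class NewickParseError(TreeError):
    """Raised when a Newick string cannot be parsed."""


# ---------------------------------------------------------------------------
# Bipartition
# ---------------------------------------------------------------------------


class Bipartition:
    """A canonical split of a taxon set induced by one branch.

    The split is stored as the side *not* containing the reference taxon
    (the lexicographically smallest label), which makes equality testing
    independent of which side a caller passes in.
    """

    __slots__ = ("taxa", "side", "_hash")

    def __init__(self, side: Iterable[str], taxa: Iterable[str]):
        taxa = frozenset(taxa)
        side = frozenset(side)
        if not side or not (taxa - side):
            raise TreeError("both sides of a bipartition must be non-empty")
        if not side <= taxa:
            raise TreeError("bipartition side is not a subset of the taxon set")
        ref = min(taxa)
        if ref in side:
            side = taxa - side
        self.taxa = taxa
        self.side = side
        self._hash = hash((self.taxa, self.side))

    @property
    def p(self) -> int:
        """Size of the smaller side."""
        return min(len(self.side), len(self.taxa) - len(self.side))

    @property
    def smaller_side(self) -> frozenset:
        other = self.taxa - self.side
        if len(self.side) < len(other):
            return self.side
        if len(other) < len(self.side):
            return other
        return self.side  # tie: canonical side

    def is_trivial(self) -> bool:
        return self.p < 2

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.taxa == other.taxa
            and self.side == other.side
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Bipartition({sorted(self.side)} | rest of {len(self.taxa)})"

    def id_string(self) -> str:
        """Stable identifier: smaller side's sorted taxa joined by '|'."""
        return "|".join(sorted(self.smaller_side))


# ---------------------------------------------------------------------------
# TreeStats
# ---------------------------------------------------------------------------


@dataclass
class TreeStats:
    median: float
    q25: float
    q75: float
    variance: float
    skewness: float
    kurtosis: float
    total_divergence: float
    mad: float


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


class Tree:
    def __init__(
        self,
        labels: Sequence[str],
        parent: np.ndarray,
        children: List[List[int]],
        blen: np.ndarray,
        root: int,
    ):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int32)
        self.children = children
        self.blen = np.asarray(blen, dtype=np.float64)
        self.root = int(root)
        self._postorder: Optional[List[int]] = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_adjacency(
        cls,
        labels: Sequence[str],
        adj: Dict[int, List[Tuple[int, float]]],
    ) -> "Tree":
        """Build from an unrooted adjacency map.

        Leaves must be numbered 0..n-1 matching ``labels``; internal nodes
        may use any other non-negative ids.  The tree is rerooted on leaf
        0's pendant edge.
        """
        n = len(labels)
        if len(set(labels)) != n:
            raise TreeError("duplicate leaf labels")
        if any(not lb for lb in labels):
            raise TreeError("empty leaf label")
        if n < 2:
            raise TreeError("need at least 2 leaves")

        # map old ids -> new ids: leaves keep 0..n-1, internals renumbered
        old_ids = sorted(adj.keys())
        internal_old = [i for i in old_ids if i >= n]
        remap = {i: i for i in range(n)}
        for k, i in enumerate(internal_old):
            remap[i] = n + k
        nnode = n + len(internal_old)
        root = nnode  # virtual root appended
        N = nnode + 1
        parent = np.full(N, -1, dtype=np.int32)
        blen = np.zeros(N, dtype=np.float64)
        children: List[List[int]] = [[] for _ in range(N)]

        if len(adj.get(0, [])) != 1:
            raise TreeError("leaf 0 must have exactly one neighbor")
        v_old, v_len = adj[0][0]

        if n == 2:
            # keep the stored split of the single edge
            parent[0] = root
            parent[1] = root
            blen[0] = v_len if v_old != 1 else 0.0
            # adj for two leaves: 0 -(L)- 1 possibly via stored halves
            if v_old == 1:
                blen[0] = 0.0
                blen[1] = v_len
            children[root] = [0, 1]
            return cls(labels, parent, children, blen, root)

        v = remap[v_old]
        parent[0] = root
        blen[0] = 0.0
        parent[v] = root
        blen[v] = v_len
        children[root] = [0, v]

        # orient the rest away from the root by DFS from v
        visited = {0, v_old}
        stack = [v_old]
        while stack:
            u_old = stack.pop()
            u = remap[u_old]
            for w_old, w_len in adj[u_old]:
                if w_old in visited:
                    continue
                visited.add(w_old)
                w = remap[w_old]
                parent[w] = u
                blen[w] = w_len
                children[u].append(w)
                stack.append(w_old)
        if len(visited) != nnode:
            raise TreeError("adjacency is not a connected tree")
        return cls(labels, parent, children, blen, root)

    def copy(self) -> "Tree":
        return Tree(
            list(self.labels),
            self.parent.copy(),
            [list(c) for c in self.children],
            self.blen.copy(),
            self.root,
        )

    # -- basic properties ----------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_binary(self) -> bool:
        return all(
            len(c) in (0, 2) for i, c in enumerate(self.children)
        )

    def postorder(self) -> List[int]:
        """Postorder node sequence (children before parents), root last."""
        if self._postorder is None:
            order: List[int] = []
            stack = [self.root]
            while stack:
                u = stack.pop()
                order.append(u)
                stack.extend(self.children[u])
            order.reverse()
            self._postorder = order
        return self._postorder

    def invalidate(self) -> None:
        """Drop cached traversals after a topology edit."""
        self._postorder = None

    def edge_nodes(self) -> List[int]:
        """Nodes representing unrooted edges (all but root and leaf 0)."""
        if self.n_leaves == 2:
            return [1]
        return [u for u in range(self.n_nodes) if u != self.root and u != 0]

    def edge_length(self, x: int) -> float:
        if self.n_leaves == 2:
            return float(self.blen[0] + self.blen[1])
        return float(self.blen[x])

    def edge_lengths(self) -> np.ndarray:
        return np.array([self.edge_length(x) for x in self.edge_nodes()])

    def internal_edge_nodes(self) -> List[int]:
        """Edge nodes for internal (bipartition-inducing) branches."""
        return [
            u
            for u in self.edge_nodes()
            if self.children[u] and self.parent[u] != self.root
        ]

    def total_divergence(self) -> float:
        return float(self.edge_lengths().sum())

    # -- subtree machinery ---------------------------------------------------

    def subtree_masks(self) -> np.ndarray:
        """Boolean [n_nodes, n_leaves]: leaves below each node."""
        n = self.n_leaves
        masks = np.zeros((self.n_nodes, n), dtype=bool)
        for u in self.postorder():
            if not self.children[u]:
                if u < n:
                    masks[u, u] = True
            else:
                for c in self.children[u]:
                    masks[u] |= masks[c]
        return masks

    def bipartition_of_edge(self, x: int) -> Bipartition:
        masks = self.subtree_masks()
        side = [self.labels[i] for i in np.flatnonzero(masks[x])]
        return Bipartition(side, self.labels)

    def neighbor_edge_nodes(self, x: int) -> List[int]:
        """The <=4 branches incident to internal edge x's endpoints."""
        p = int(self.parent[x])
        if p == self.root or not self.children[x]:
            raise TreeError("neighbor branches are defined for internal edges")
        sib = [c for c in self.children[p] if c != x]
        return list(self.children[x]) + sib + [p]

    # -- Newick output -------------------------------------------------------

    def to_newick(
        self,
        supports: Optional[Dict[int, float]] = None,
        length_fmt: str = "%.10g",
    ) -> str:
        """Write Newick.  ``supports`` maps edge nodes to values written as
        internal node labels (3 decimals)."""
        if self.n_leaves == 2:
            a, b = self.labels
            return "(%s:%s,%s:%s);" % (
                _quote(a),
                length_fmt % self.blen[0],
                _quote(b),
                length_fmt % self.blen[1],
            )

        def write(u: int, length: float) -> str:
            if not self.children[u]:
                return "%s:%s" % (_quote(self.labels[u]), length_fmt % length)
            inner = ",".join(write(c, self.blen[c]) for c in self.children[u])
            label = ""
            if supports is not None and u in supports:
                label = "%.3f" % supports[u]
            return "(%s)%s:%s" % (inner, label, length_fmt % length)

        # standard unrooted style: base at leaf 0's neighbor
        v = [c for c in self.children[self.root] if c != 0][0]
        parts = [
            "%s:%s" % (_quote(self.labels[0]), length_fmt % self.blen[v])
        ] + [write(c, self.blen[c]) for c in self.children[v]]
        return "(%s);" % ",".join(parts)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick parsing (via dendropy)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into an unrooted :class:`Tree`.

    Missing branch lengths default to 0; internal node labels are ignored
    on read.  Degree-2 nodes (rooted-style basal bifurcations) are
    suppressed, except in the 2-leaf case where the stored split of the
    single edge is kept.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    dn_leaves = [lf for lf in dt.leaf_node_iter()]
    labels = [
        (lf.taxon.label if lf.taxon is not None else (lf.label or ""))
        for lf in dn_leaves
    ]
    if any(not lb for lb in labels):
        raise TreeError("empty leaf label")
    if len(set(labels)) != len(labels):
        dup = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise TreeError(f"duplicate leaf label(s): {dup}")

    # assign ids
    ids: Dict[int, int] = {}
    for i, lf in enumerate(dn_leaves):
        ids[id(lf)] = i
    nxt = len(labels)
    for nd in dt.preorder_node_iter():
        if id(nd) not in ids:
            ids[id(nd)] = nxt
            nxt += 1

    adj: Dict[int, List[Tuple[int, float]]] = {i: [] for i in range(nxt)}
    for nd in dt.preorder_node_iter():
        pa = nd.parent_node
        if pa is None:
            continue
        u, v = ids[id(pa)], ids[id(nd)]
        ln = float(nd.edge.length) if nd.edge.length is not None else 0.0
        adj[u].append((v, ln))
        adj[v].append((u, ln))

    n = len(labels)
    if n < 2:
        raise TreeError("need at least 2 leaves")
    if n > 2:
        # suppress degree-2 internal nodes (e.g. a rooted basal bifurcation)
        changed = True
        while changed:
            changed = False
            for u in list(adj.keys()):
                if u >= n and len(adj[u]) == 2:
                    (a, la), (b, lb) = adj[u]
                    adj[a] = [(w, l) for (w, l) in adj[a] if w != u]
                    adj[b] = [(w, l) for (w, l) in adj[b] if w != u]
                    adj[a].append((b, la + lb))
                    adj[b].append((a, la + lb))
                    del adj[u]
                    changed = True
    else:
        # 2 leaves: record halves of the single edge explicitly
        la = adj[0][0][1] if adj[0] else 0.0
        lb = adj[1][0][1] if adj[1] else 0.0
        tree = Tree.from_adjacency(labels, {0: [(1, la + lb)], 1: [(0, la + lb)]})
        tree.blen[0] = la
        tree.blen[1] = lb
        return tree

    return Tree.from_adjacency(labels, adj)


def write_newick(tree: Tree, supports: Optional[Dict[int, float]] = None) -> str:
    return tree.to_newick(supports=supports)


# ---------------------------------------------------------------------------
# Bipartition operations
# ---------------------------------------------------------------------------


def extract_bipartitions(tree: Tree) -> List[Bipartition]:
    """All nontrivial bipartitions of an unrooted binary tree, one per
    internal branch (n-3 of them); empty for n < 4."""
    if tree.n_leaves < 4:
        return []
    if not tree.is_binary():
        raise TreeError("bipartition extraction requires a binary tree")
    masks = tree.subtree_masks()
    out = []
    for x in tree.internal_edge_nodes():
        side = [tree.labels[i] for i in np.flatnonzero(masks[x])]
        out.append(Bipartition(side, tree.labels))
    return out


def bipartition_in_tree(bip: Bipartition, tree: Tree) -> bool:
    if bip.taxa != frozenset(tree.labels):
        raise TreeError("bipartition taxa do not match the tree's leaf set")
    return bip in set(extract_bipartitions(tree))


def _side_vector(bip: Bipartition, labels: Sequence[str]) -> np.ndarray:
    index = {lb: i for i, lb in enumerate(labels)}
    v = np.zeros(len(labels), dtype=bool)
    for lb in bip.side:
        v[index[lb]] = True
    return v


def transfer_distance(bip: Bipartition, tree: Tree) -> int:
    """Minimum Hamming distance between ``bip`` and any internal branch of
    ``tree``, minimized over both side pairings and capped at p-1.

    0 iff the bipartition is present; a tree with no internal branch
    returns the theoretical maximum p-1.
    """
    if bip.taxa != frozenset(tree.labels):
        raise TreeError("bipartition taxa do not match the tree's leaf set")
    n = tree.n_leaves
    p = bip.p
    internal = tree.internal_edge_nodes()
    if not internal:
        return p - 1
    masks = tree.subtree_masks()[internal]  # [E, n]
    b = _side_vector(bip, tree.labels)
    ham = (masks ^ b).sum(axis=1)
    d = int(np.minimum(ham, n - ham).min())
    return min(d, p - 1)


# ---------------------------------------------------------------------------
# Tree statistics
# ---------------------------------------------------------------------------


def tree_branch_stats(tree: Tree) -> TreeStats:
    """Moments of the branch-length distribution over all edges (internal
    and terminal), total divergence, and the ultrametricity deviation.

    Skewness and excess kurtosis use population (biased) moments and are 0
    for degenerate (all-equal) length sets.
    """
    x = tree.edge_lengths()
    if x.size == 0:
        raise TreeError("tree has no branches")
    med = float(np.median(x))
    q25, q75 = (float(v) for v in np.percentile(x, [25, 75]))
    var = float(np.var(x))
    if var < 1e-24:
        skew = kurt = 0.0
    else:
        m = x.mean()
        s = math.sqrt(var)
        skew = float(np.mean(((x - m) / s) ** 3))
        kurt = float(np.mean(((x - m) / s) ** 4) - 3.0)
    return TreeStats(
        median=med,
        q25=q25,
        q75=q75,
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        total_divergence=float(x.sum()),
        mad=mad_ultrametricity(tree),
    )


def _node_leaf_distances(tree: Tree) -> np.ndarray:
    """Distance from every node to every leaf, [n_nodes, n_leaves]."""
    n = tree.n_leaves
    N = tree.n_nodes
    dist = np.zeros((N, n))
    reach = np.zeros((N, n), dtype=bool)
    post = tree.postorder()
    for u in post:
        if not tree.children[u]:
            if u < n:
                reach[u, u] = True
        else:
            for c in tree.children[u]:
                dist[u, reach[c]] = dist[c, reach[c]] + tree.blen[c]
                reach[u] |= reach[c]
    for u in reversed(post):  # preorder
        for c in tree.children[u]:
            out = ~reach[c]
            dist[c, out] = dist[u, out] + tree.blen[c]
            reach[c] |= out
    return dist


def mad_ultrametricity(tree: Tree) -> float:
    """Minimal-ancestor-deviation departure from a molecular clock.

    For each candidate root position (optimized continuously along every
    edge) the relative deviation of each leaf pair (i, j) is
    (d(root,i) - d(root,j)) / d(i,j); the score of a position is the RMS
    over pairs, and the tree's score is the minimum over positions.  0 for
    a perfectly clock-like tree; scale-invariant; in [0, 1].
    """
    n = tree.n_leaves
    if n < 2:
        raise TreeError("need at least 2 leaves")
    total = tree.total_divergence()
    if total <= 0:
        return 0.0
    if n == 2:
        a, b = float(tree.blen[0]), float(tree.blen[1])
        return abs(a - b) / (a + b)

    dist = _node_leaf_distances(tree)
    masks = tree.subtree_masks()
    D = dist[:n, :]  # leaf rows of the node-leaf matrix are path distances
    iu, ju = np.triu_indices(n, k=1)
    best = math.inf
    for x in tree.edge_nodes():
        p = int(tree.parent[x])
        L = tree.edge_length(x)
        inside = masks[x]
        base = np.where(inside, dist[x], dist[p] + L)
        sigma = np.where(inside, 1.0, -1.0)
        P0 = base[iu] - base[ju]
        P1 = sigma[iu] - sigma[ju]
        Dij = D[iu, ju]
        ok = Dij > 0
        P0 = np.where(ok, P0 / np.where(ok, Dij, 1.0), 0.0)
        P1 = np.where(ok, P1 / np.where(ok, Dij, 1.0), 0.0)
        A = float((P1 * P1).sum())
        B = float(2.0 * (P0 * P1).sum())
        C = float((P0 * P0).sum())
        t = 0.0 if A <= 0 else min(max(-B / (2 * A), 0.0), L)
        ss = C + B * t + A * t * t
        best = min(best, ss)
    npairs = iu.size
    return float(math.sqrt(max(best, 0.0) / npairs))


def subtree_side_stats(bip: Bipartition, tree: Tree) -> Tuple[int, float, float, float]:
    """(leaf count, leaf fraction, divergence sum, divergence fraction) on
    the smaller-or-equal side of an internal branch of ``tree``.

    The partition branch itself is excluded from the side's divergence sum;
    the fraction is relative to the total tree divergence.
    """
    masks = tree.subtree_masks()
    n = tree.n_leaves
    target = _side_vector(bip, tree.labels)
    edge = None
    for x in tree.internal_edge_nodes():
        if np.array_equal(masks[x], target) or np.array_equal(~masks[x], target):
            edge = x
            break
    if edge is None:
        raise TreeError("bipartition is not an internal branch of the tree")
    inside_count = int(masks[edge].sum())
    use_inside = inside_count <= n - inside_count
    # at a tie prefer the canonical stored side
    if inside_count == n - inside_count:
        inside_labels = frozenset(
            tree.labels[i] for i in np.flatnonzero(masks[edge])
        )
        use_inside = inside_labels == bip.side
    total = tree.total_divergence()
    inside_nodes = [
        u
        for u in tree.edge_nodes()
        if u != edge and bool(np.all(~masks[u] | masks[edge]))
    ]
    inside_sum = float(sum(tree.edge_length(u) for u in inside_nodes))
    if use_inside:
        count = inside_count
        div = inside_sum
    else:
        count = n - inside_count
        div = total - inside_sum - tree.edge_length(edge)
    return count, count / n, div, (div / total if total > 0 else 0.0)


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Number of nontrivial bipartitions present in exactly one tree."""
    sa = set(extract_bipartitions(a))
    sb = set(extract_bipartitions(b))
    return len(sa ^ sb)
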