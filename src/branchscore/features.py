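"""Per-bipartition feature extraction.

One row per internal branch of the inferred ML tree; 39 features spanning
alignment summaries, branch-length geometry, parsimony-tree and
suboptimal-tree concordance (presence fractions and transfer distances),
and the NNI log-likelihood differences.  Features that are undefined for
a given instance (no internal neighbor bipartitions, fewer than two
suboptimal trees) are encoded as NaN and handled natively by the
tree-ensemble learner rather than imputed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inference import (
    LikelihoodEngine,
    ParsimonyTreeSet,
    SearchResult,
    nni_ll_diffs_all,
)
from .phylo import Bipartition, Tree, TreeError, tree_branch_stats
from .seqsim import MSA, SubstitutionModel

# canonical column order (f1..f39)
FEATURE_COLUMNS: List[str] = [
    "n_seqs",                    # f1
    "n_sites",                   # f2
    "n_unique_sites",            # f3
    "frac_constant_sites",       # f4
    "difficulty",                # f5
    "branch_length",             # f6
    "bl_over_tree_mean",         # f7
    "bl_over_neighbor_mean",     # f8
    "bl_median",                 # f9
    "bl_q25",                    # f10
    "bl_q75",                    # f11
    "bl_variance",               # f12
    "bl_skewness",               # f13
    "bl_kurtosis",               # f14
    "total_divergence",          # f15
    "mad_ultrametricity",        # f16
    "side_leaf_count",           # f17
    "side_leaf_fraction",        # f18
    "side_divergence",           # f19
    "side_divergence_fraction",  # f20
    "neighbor_bl_mean",          # f21
    "neighbor_bl_min",           # f22
    "neighbor_bl_max",           # f23
    "neighbor_bl_min_max_ratio", # f24
    "neighbor_bl_variance",      # f25
    "parsimony_presence",        # f26
    "parsimony_transfer_mean",   # f27
    "nbr_parsimony_presence_mean",   # f28
    "nbr_parsimony_presence_min",    # f29
    "nbr_parsimony_transfer_mean",   # f30
    "nbr_parsimony_transfer_min",    # f31
    "subopt_presence",           # f32
    "subopt_transfer_mean",      # f33
    "nbr_subopt_presence_mean",  # f34
    "nbr_subopt_presence_min",   # f35
    "nbr_subopt_transfer_mean",  # f36
    "nbr_subopt_transfer_min",   # f37
    "nni_ll_diff_min",           # f38
    "nni_ll_diff_max",           # f39
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _canonical_split_masks(tree: Tree, labels: Sequence[str]) -> np.ndarray:
    """Canonical boolean side vectors for all internal edges, with
    columns in the given reference label order and the reference taxon
    (smallest label) excluded from the stored side; [E, n]."""
    masks = tree.subtree_masks()
    internal = tree.internal_edge_nodes()
    out = masks[internal]
    if list(tree.labels) != list(labels):
        pos = {lb: i for i, lb in enumerate(tree.labels)}
        out = out[:, [pos[lb] for lb in labels]]
    else:
        out = out.copy()
    ref_idx = int(np.argmin(np.asarray(labels)))
    flip = out[:, ref_idx]
    out[flip] = ~out[flip]
    return out


def _presence_and_transfer(
    bip_masks: np.ndarray, trees: Sequence[Tree], labels: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """For each query split (canonical mask rows), fraction of trees that
    contain it and mean raw transfer distance across trees."""
    K, n = bip_masks.shape
    p_small = np.minimum(bip_masks.sum(axis=1), n - bip_masks.sum(axis=1))
    presence = np.zeros(K)
    tdist = np.zeros(K)
    for tr in trees:
        tmasks = _canonical_split_masks(tr, labels)
        if tmasks.shape[0] == 0:
            tdist += p_small - 1
            continue
        ham = (tmasks[None, :, :] ^ bip_masks[:, None, :]).sum(axis=2)
        d = np.minimum(ham, n - ham).min(axis=1)
        d = np.minimum(d, p_small - 1)
        d = np.maximum(d, 0)
        presence += d == 0
        tdist += d
    m = len(trees)
    return presence / m, tdist / m


def _side_stats_all(tree: Tree) -> Dict[int, Tuple[int, float, float, float]]:
    """(count, fraction, divergence, divergence fraction) of the
    smaller-or-equal side for every internal edge node."""
    n = tree.n_leaves
    total = tree.total_divergence()
    masks = tree.subtree_masks()
    inside_sum = np.zeros(tree.n_nodes)
    for u in tree.postorder():
        for c in tree.children[u]:
            inside_sum[u] += inside_sum[c] + tree.edge_length(c)
    out = {}
    for x in tree.internal_edge_nodes():
        cnt_in = int(masks[x].sum())
        div_in = inside_sum[x]
        if cnt_in <= n - cnt_in:
            cnt, div = cnt_in, div_in
        else:
            cnt = n - cnt_in
            div = total - div_in - tree.edge_length(x)
        out[x] = (cnt, cnt / n, float(div), float(div / total) if total > 0 else 0.0)
    return out


def neighbor_branches(tree: Tree, branch: Bipartition) -> List[float]:
    """Lengths of the <=4 branches incident to an internal branch's two
    endpoints (terminal branches included)."""
    from .inference import _find_edge

    x = _find_edge(tree, branch)
    return [tree.edge_length(u) for u in tree.neighbor_edge_nodes(x)]


# ---------------------------------------------------------------------------
# difficulty proxy
# ---------------------------------------------------------------------------


def difficulty_proxy(msa: MSA, ptrees: ParsimonyTreeSet) -> float:
    """Alignment difficulty score in [0, 1] (higher = harder).

    Average of (a) the mean normalized Robinson-Foulds distance among the
    parsimony-tree sample (topological instability of cheap trees) and
    (b) the fraction of alignment columns that vary but are parsimony-
    uninformative (weak, noisy signal).
    """
    trees = ptrees.trees
    if len(trees) < 2:
        raise ValueError("need at least 2 parsimony trees")
    n = msa.n_seqs
    labels = sorted(msa.labels)
    keysets = []
    for tr in trees:
        tm = _canonical_split_masks(tr, labels)
        keysets.append({row.tobytes() for row in tm})
    denom = n - 3
    pairs = 0
    acc = 0.0
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            inter = len(keysets[i] & keysets[j])
            rf = (len(keysets[i]) - inter) + (len(keysets[j]) - inter)
            acc += rf / (2 * denom) if denom > 0 else 0.0
            pairs += 1
    rf_term = acc / pairs

    # variable-but-uninformative columns
    counts = _state_counts(msa.codes)  # [sites, 4]
    n_states = (counts > 0).sum(axis=1)
    informative = (counts >= 2).sum(axis=1) >= 2
    uninf = int(((n_states >= 2) & ~informative).sum())
    uninf_term = uninf / msa.n_sites
    return float(0.5 * rf_term + 0.5 * uninf_term)


def _state_counts(codes: np.ndarray) -> np.ndarray:
    """Per-column counts of each nucleotide (gaps ignored); [sites, 4]."""
    out = np.zeros((codes.shape[1], 4), dtype=np.int32)
    for s in range(4):
        out[:, s] = (codes == s).sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# main extraction
# ---------------------------------------------------------------------------


def compute_features(
    msa: MSA,
    result: SearchResult,
    ptrees: ParsimonyTreeSet,
    model: SubstitutionModel,
    engine: Optional[LikelihoodEngine] = None,
    msa_id: str = "msa0",
    difficulty: Optional[float] = None,
) -> pd.DataFrame:
    """Feature table for every internal branch of the inferred tree.

    ``difficulty`` overrides the built-in proxy with an externally
    computed score (e.g. an alignment-difficulty predictor).
    """
    tree = result.best_tree
    if not tree.is_binary():
        raise TreeError("inferred tree must be binary")
    if list(tree.labels) != list(msa.labels):
        raise TreeError("tree and alignment leaf sets differ")
    engine = engine or LikelihoodEngine(msa, model)
    n = tree.n_leaves
    internal = tree.internal_edge_nodes()
    K = len(internal)
    bip_masks = _canonical_split_masks(tree, tree.labels)

    # alignment-level
    f1 = float(n)
    f2 = float(msa.n_sites)
    patterns = engine.patterns
    f3 = float(patterns.shape[1])
    counts = _state_counts(patterns)
    constant = (counts > 0).sum(axis=1) == 1
    f4 = float(engine.weights[constant].sum() / msa.n_sites)
    f5 = difficulty if difficulty is not None else difficulty_proxy(msa, ptrees)

    # tree-level
    stats = tree_branch_stats(tree)
    all_lengths = tree.edge_lengths()
    mean_bl = float(all_lengths.mean())
    side_stats = _side_stats_all(tree)

    # parsimony concordance
    pars_presence, pars_transfer = _presence_and_transfer(
        bip_masks, ptrees.trees, tree.labels
    )
    # suboptimal-tree concordance
    sub_trees = [t for t, _ in result.suboptimal]
    have_subopt = len(sub_trees) >= 2
    if have_subopt:
        sub_presence, sub_transfer = _presence_and_transfer(
            bip_masks, sub_trees, tree.labels
        )
    else:
        sub_presence = np.full(K, np.nan)
        sub_transfer = np.full(K, np.nan)

    # NNI log-likelihood differences
    nni = nni_ll_diffs_all(tree, engine, best_ll=result.best_ll)

    edge_pos = {x: i for i, x in enumerate(internal)}
    rows = []
    for i, x in enumerate(internal):
        nbr_nodes = tree.neighbor_edge_nodes(x)
        nbr_lengths = np.array([tree.edge_length(u) for u in nbr_nodes])
        nbr_internal = [u for u in nbr_nodes if u in edge_pos]
        f6 = tree.edge_length(x)
        f8 = f6 / nbr_lengths.mean() if nbr_lengths.mean() > 0 else np.nan
        nmax = nbr_lengths.max()
        ratio = nbr_lengths.min() / nmax if nmax > 0 else 1.0
        cnt, frac, div, divfrac = side_stats[x]
        if nbr_internal:
            idx = [edge_pos[u] for u in nbr_internal]
            f28 = float(pars_presence[idx].mean())
            f29 = float(pars_presence[idx].min())
            f30 = float(pars_transfer[idx].mean())
            f31 = float(pars_transfer[idx].min())
            if have_subopt:
                f34 = float(sub_presence[idx].mean())
                f35 = float(sub_presence[idx].min())
                f36 = float(sub_transfer[idx].mean())
                f37 = float(sub_transfer[idx].min())
            else:
                f34 = f35 = f36 = f37 = np.nan
        else:
            f28 = f29 = f30 = f31 = f34 = f35 = f36 = f37 = np.nan
        dmin, dmax = nni[x]
        side_labels = [tree.labels[k] for k in np.flatnonzero(bip_masks[i])]
        bip = Bipartition(side_labels, tree.labels)
        rows.append(
            {
                "msa_id": msa_id,
                "bipartition_id": bip.id_string(),
                "edge_node": x,
                "n_seqs": f1,
                "n_sites": f2,
                "n_unique_sites": f3,
                "frac_constant_sites": f4,
                "difficulty": f5,
                "branch_length": f6,
                "bl_over_tree_mean": f6 / mean_bl if mean_bl > 0 else np.nan,
                "bl_over_neighbor_mean": f8,
                "bl_median": stats.median,
                "bl_q25": stats.q25,
                "bl_q75": stats.q75,
                "bl_variance": stats.variance,
                "bl_skewness": stats.skewness,
                "bl_kurtosis": stats.kurtosis,
                "total_divergence": stats.total_divergence,
                "mad_ultrametricity": stats.mad,
                "side_leaf_count": float(cnt),
                "side_leaf_fraction": frac,
                "side_divergence": div,
                "side_divergence_fraction": divfrac,
                "neighbor_bl_mean": float(nbr_lengths.mean()),
                "neighbor_bl_min": float(nbr_lengths.min()),
                "neighbor_bl_max": float(nmax),
                "neighbor_bl_min_max_ratio": float(ratio),
                "neighbor_bl_variance": float(nbr_lengths.var()),
                "parsimony_presence": float(pars_presence[i]),
                "parsimony_transfer_mean": float(pars_transfer[i]),
                "nbr_parsimony_presence_mean": f28,
                "nbr_parsimony_presence_min": f29,
                "nbr_parsimony_transfer_mean": f30,
                "nbr_parsimony_transfer_min": f31,
                "subopt_presence": float(sub_presence[i]),
                "subopt_transfer_mean": float(sub_transfer[i]),
                "nbr_subopt_presence_mean": f34,
                "nbr_subopt_presence_min": f35,
                "nbr_subopt_transfer_mean": f36,
                "nbr_subopt_transfer_min": f37,
                "nni_ll_diff_min": dmin,
                "nni_ll_diff_max": dmax,
            }
        )
    df = pd.DataFrame(rows, columns=["msa_id", "bipartition_id", "edge_node"] + FEATURE_COLUMNS)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """TSV with the stable documented column order."""
    cols = ["msa_id", "bipartition_id"] + FEATURE_COLUMNS + [
        c for c in ("label",) if c in df.columns
    ]
    df.to_csv(path, sep="\t", index=False, columns=cols)
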