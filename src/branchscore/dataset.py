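"""Labeling against the true tree and grouped, stratified splitting.

Every bipartition of an inferred tree is labeled 1 iff it occurs in the
true (generating) tree.  All rows of one alignment share a group id, and
groups are never split across train/test or across cross-validation
folds, so no tree leaks information between partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phylo import Tree, TreeError, extract_bipartitions


class DatasetError(ValueError):
    pass


def label_bipartitions(inferred: Tree, true_tree: Tree) -> np.ndarray:
    """0/1 label per internal branch of ``inferred`` (in
    ``internal_edge_nodes`` order): 1 iff present in ``true_tree``.

    The number of 1-labels equals (n-3) - RF/2 for binary trees, where RF
    is the Robinson-Foulds distance.
    """
    if set(inferred.labels) != set(true_tree.labels):
        raise TreeError("leaf sets differ between inferred and true tree")
    true_set = set(extract_bipartitions(true_tree))
    labels = []
    for x in inferred.internal_edge_nodes():
        labels.append(1 if inferred.bipartition_of_edge(x) in true_set else 0)
    return np.array(labels, dtype=np.int8)


@dataclass
class DatasetSplit:
    train: pd.DataFrame
    test: pd.DataFrame
    train_groups: List[str]
    test_groups: List[str]
    bin_edges: Optional[np.ndarray] = None

    @property
    def base_rates(self) -> Tuple[float, float]:
        return float(self.train["label"].mean()), float(self.test["label"].mean())

    def manifest(self) -> dict:
        return {
            "train_msas": sorted(self.train_groups),
            "test_msas": sorted(self.test_groups),
            "train_label_rate": float(self.train["label"].mean()),
            "test_label_rate": float(self.test["label"].mean()),
        }


def stratified_group_split(
    table: pd.DataFrame,
    train_frac: float = 0.7,
    n_bins: int = 5,
    seed: int = 0,
) -> DatasetSplit:
    """Group-disjoint 70/30 split, stratified by sequence count.

    Alignments are binned into ``n_bins`` equal-size quantile bins of
    their sequence count and ``train_frac`` of the alignments in each bin
    go to the training partition.
    """
    rng = np.random.default_rng(seed)
    per_msa = table.groupby("msa_id")["n_seqs"].first()
    msas = per_msa.index.to_numpy()
    if msas.size < n_bins:
        warnings.warn("fewer alignments than bins; falling back to one bin")
        bins = pd.Series(0, index=per_msa.index)
        edges = None
    else:
        binned, edges = pd.qcut(
            per_msa.rank(method="first"), n_bins, labels=False, retbins=True
        )
        bins = pd.Series(binned, index=per_msa.index)
    train_ids: List[str] = []
    test_ids: List[str] = []
    for b in sorted(bins.unique()):
        ids = np.sort(bins.index[bins == b].to_numpy())
        rng.shuffle(ids)
        k = int(round(train_frac * ids.size))
        train_ids.extend(ids[:k])
        test_ids.extend(ids[k:])
    train = table[table["msa_id"].isin(train_ids)].reset_index(drop=True)
    test = table[table["msa_id"].isin(test_ids)].reset_index(drop=True)
    assert not (set(train_ids) & set(test_ids))
    return DatasetSplit(
        train=train,
        test=test,
        train_groups=sorted(train_ids),
        test_groups=sorted(test_ids),
        bin_edges=None if edges is None else np.asarray(edges),
    )


def group_kfold(
    groups: Sequence[str], k: int = 5, seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Row-index folds with whole groups per fold, balanced by group
    count (+/-1).  Returns [(train_idx, test_idx), ...]."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < k:
        raise DatasetError(f"need at least {k} groups, got {uniq.size}")
    rng = np.random.default_rng(seed)
    order = uniq.copy()
    rng.shuffle(order)
    fold_of_group = {g: i % k for i, g in enumerate(order)}
    fold_rows = np.array([fold_of_group[g] for g in groups])
    out = []
    for f in range(k):
        test_idx = np.flatnonzero(fold_rows == f)
        train_idx = np.flatnonzero(fold_rows != f)
        assert not (set(groups[test_idx]) & set(groups[train_idx]))
        out.append((train_idx, test_idx))
    return out
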