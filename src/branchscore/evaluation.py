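"""Discrimination, thresholded-classification, and calibration metrics.

AUC is the probability that a random correct branch outranks a random
incorrect one; thresholded metrics use the cutoff C (default 0.5, strict
inequality); the expected calibration error (ECE) uses 30 equal-width
bins over [0, 1] with empty bins contributing zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import log_loss, roc_auc_score


class EvaluationError(ValueError):
    pass


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank formula; ties count one half)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise EvaluationError("AUC undefined: a single class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def classification_metrics(
    scores: Sequence[float], labels: Sequence[int], C: float = 0.5
) -> Dict[str, float]:
    """Confusion matrix at cutoff C (predict 1 iff score > C), with MCC,
    FPR, FNR, and F1; MCC is 0 when a denominator factor vanishes."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    yhat = (s > C).astype(int)
    tp = int(((yhat == 1) & (y == 1)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    fnr = fn / (fn + tp) if (fn + tp) > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return {
        "mcc": float(mcc),
        "fpr": float(fpr),
        "fnr": float(fnr),
        "f1": float(f1),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def ece(scores: Sequence[float], labels: Sequence[int], n_bins: int = 30) -> float:
    """Expected calibration error over equal-width bins of [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.size == 0:
        raise EvaluationError("no scores")
    if np.any((s < 0) | (s > 1)):
        raise EvaluationError("scores must lie in [0, 1]")
    idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    total = 0.0
    n = s.size
    for b in range(n_bins):
        m = idx == b
        nb = int(m.sum())
        if nb == 0:
            continue
        total += (nb / n) * abs(s[m].mean() - y[m].mean())
    return float(total)


def calibration_curve_points(
    scores: Sequence[float], labels: Sequence[int], n_bins: int = 30
) -> pd.DataFrame:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append(
            {
                "bin": b,
                "lo": b / n_bins,
                "hi": (b + 1) / n_bins,
                "count": int(m.sum()),
                "mean_pred": float(s[m].mean()) if m.any() else np.nan,
                "frac_pos": float(y[m].mean()) if m.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PerGroupComparison:
    per_group: pd.DataFrame
    n_valid: int
    n_skipped: int
    p_value: Optional[float]


def per_msa_auc_comparison(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    groups: Sequence[str],
) -> PerGroupComparison:
    """Per-alignment AUC for two scorers plus a two-sided Wilcoxon
    signed-rank test on the paired per-alignment AUCs.  Groups with a
    single class are skipped (and counted); fewer than 10 valid pairs
    yields descriptives only."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    rows = []
    skipped = 0
    for grp in np.unique(g):
        m = g == grp
        if np.unique(y[m]).size < 2:
            skipped += 1
            continue
        rows.append(
            {
                "msa_id": grp,
                "auc_a": roc_auc_score(y[m], sa[m]),
                "auc_b": roc_auc_score(y[m], sb[m]),
            }
        )
    df = pd.DataFrame(rows)
    p = None
    if len(df) >= 10:
        d = df["auc_a"] - df["auc_b"]
        if np.allclose(d, 0):
            p = 1.0
        else:
            method = "exact" if len(d) <= 25 else "approx"
            try:
                p = float(wilcoxon(d, alternative="two-sided", method=method).pvalue)
            except ValueError:
                p = float(wilcoxon(d, alternative="two-sided").pvalue)
    return PerGroupComparison(
        per_group=df, n_valid=len(df), n_skipped=skipped, p_value=p
    )


@dataclass
class EvaluationReport:
    auc: float
    mcc: float
    fpr: float
    fnr: float
    f1: float
    ece: float
    log_loss: float
    n: int
    base_rate: float
    confusion: Dict[str, int]
    calibration: Optional[pd.DataFrame] = None
    per_msa_auc: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("auc", "mcc", "fpr", "fnr", "f1", "ece", "log_loss", "n", "base_rate")
        }
        d["confusion"] = self.confusion
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    groups: Optional[Sequence[str]] = None,
    C: float = 0.5,
    n_bins: int = 30,
) -> EvaluationReport:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    cm = classification_metrics(s, y, C=C)
    per_msa = None
    if groups is not None:
        g = np.asarray(groups)
        rows = []
        for grp in np.unique(g):
            m = g == grp
            if np.unique(y[m]).size < 2:
                continue
            rows.append({"msa_id": grp, "auc": roc_auc_score(y[m], s[m])})
        per_msa = pd.DataFrame(rows)
    eps = 1e-12
    return EvaluationReport(
        auc=auc(s, y),
        mcc=cm["mcc"],
        fpr=cm["fpr"],
        fnr=cm["fnr"],
        f1=cm["f1"],
        ece=ece(s, y, n_bins=n_bins),
        log_loss=float(log_loss(y, np.clip(s, eps, 1 - eps))),
        n=int(y.size),
        base_rate=float(y.mean()),
        confusion={k: cm[k] for k in ("tp", "tn", "fp", "fn")},
        calibration=calibration_curve_points(s, y, n_bins=n_bins),
        per_msa_auc=per_msa,
    )


def auc_by_bins(
    scores: Sequence[float],
    labels: Sequence[int],
    values: Sequence[float],
    n_bins: int = 30,
) -> pd.DataFrame:
    """AUC within quantile bins of a numeric factor (alignment size,
    difficulty, split depth, ...)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    v = np.asarray(values, dtype=float)
    ranks = pd.Series(v).rank(method="first")
    try:
        bins = pd.qcut(ranks, min(n_bins, ranks.nunique()), labels=False)
    except ValueError:
        bins = pd.Series(np.zeros(len(v), dtype=int))
    rows = []
    for b in sorted(pd.unique(bins)):
        m = (bins == b).to_numpy()
        if np.unique(y[m]).size < 2:
            continue
        rows.append(
            {
                "bin": int(b),
                "median_value": float(np.median(v[m])),
                "n": int(m.sum()),
                "auc": roc_auc_score(y[m], s[m]),
            }
        )
    return pd.DataFrame(rows)


def learning_curve(
    table_train: pd.DataFrame,
    table_test: pd.DataFrame,
    train_fn: Callable[[pd.DataFrame], object],
    predict_fn: Callable[[object, pd.DataFrame], np.ndarray],
    msa_counts: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Test log-loss as a function of the number of training alignments.

    Alignments (not rows) are subsampled with a fixed seed; the test set
    is held constant across counts.
    """
    counts = list(msa_counts)
    if counts != sorted(counts):
        raise EvaluationError("msa_counts must be ascending")
    rng = np.random.default_rng(seed)
    groups = np.sort(table_train["msa_id"].unique())
    order = groups.copy()
    rng.shuffle(order)
    y_test = table_test["label"].to_numpy(dtype=int)
    eps = 1e-12
    rows = []
    for c in counts:
        if c > groups.size:
            raise EvaluationError(f"only {groups.size} training alignments available")
        keep = set(order[:c])
        sub = table_train[table_train["msa_id"].isin(keep)]
        model = train_fn(sub)
        p = np.clip(predict_fn(model, table_test), eps, 1 - eps)
        rows.append(
            {
                "n_msas": c,
                "log_loss": float(log_loss(y_test, p)),
                "auc": float(roc_auc_score(y_test, p)),
            }
        )
    return pd.DataFrame(rows)
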