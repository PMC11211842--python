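"""Gradient-boosted branch-support classifier: tuning, feature
elimination, isotonic calibration, and importance reporting.

The primary backend is LightGBM; random-forest and two-layer MLP
backends run through the identical pipeline for comparison.  Calibration
fits one isotonic regression per cross-validation fold on that fold's
out-of-fold raw predictions; at predict time the refit ensemble's raw
score is passed through the average of the fold calibrators, which is a
monotone map and therefore preserves the raw ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

import lightgbm as lgb

from .dataset import group_kfold
from .features import FEATURE_COLUMNS


class MLError(ValueError):
    pass


# the hyperparameter grid of the boosted-tree model
DEFAULT_GRID: Dict[str, List] = {
    "num_leaves": [25, 50, 100, 200],
    "max_depth": [3, 6, 12, -1],  # -1 = unlimited depth
    "learning_rate": [0.1, 0.01, 0.001],
    "n_estimators": [100, 300],
    "subsample": [0.6, 0.8, 1.0],
}

RF_GRID: Dict[str, List] = {
    "max_depth": [3, 5, 10],
    "min_samples_split": [2, 5, 10],
}

MLP_GRID: Dict[str, List] = {
    "hidden_layer_sizes": [(10, 3), (30, 5), (50, 10)],
    "alpha": [0.0001, 0.05],
}

_DEFAULT_PARAMS = {
    "num_leaves": 50,
    "max_depth": -1,
    "learning_rate": 0.1,
    "n_estimators": 100,
    "subsample": 1.0,
}


@dataclass
class ModelConfig:
    backend: str = "gbm"  # gbm | rf | mlp
    grid: Optional[Dict[str, List]] = None
    cv_folds: int = 5
    seed: int = 0
    max_grid_configs: int = 12  # seeded subsample cap on the full grid
    run_rfe: bool = False
    rfe_tol: float = 1e-4

    def full_grid(self) -> List[Dict]:
        grid = self.grid
        if grid is None:
            grid = {
                "gbm": DEFAULT_GRID,
                "rf": RF_GRID,
                "mlp": MLP_GRID,
            }[self.backend]
        keys = list(grid)
        return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]

    def sampled_grid(self) -> List[Dict]:
        configs = self.full_grid()
        if len(configs) <= self.max_grid_configs:
            return configs
        rng = np.random.default_rng(self.seed)
        idx = rng.choice(len(configs), size=self.max_grid_configs, replace=False)
        return [configs[i] for i in sorted(idx)]


def _make_estimator(backend: str, params: Dict, seed: int):
    if backend == "gbm":
        p = dict(params)
        return lgb.LGBMClassifier(
            objective="binary",
            random_state=seed,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
            subsample_freq=1 if p.get("subsample", 1.0) < 1.0 else 0,
            **p,
        )
    if backend == "rf":
        return RandomForestClassifier(
            n_estimators=300, random_state=seed, n_jobs=1, **params
        )
    if backend == "mlp":
        return MLPClassifier(
            max_iter=500, random_state=seed, **params
        )
    raise MLError(f"unknown backend {backend!r}")


def _xy(table: pd.DataFrame, features: Sequence[str]):
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise MLError(f"missing feature column(s): {missing}")
    X = table[list(features)].astype(float).reset_index(drop=True)
    y = table["label"].to_numpy(dtype=int)
    return X, y


def _prep_X(X: pd.DataFrame, backend: str) -> pd.DataFrame:
    """NaN-encoded masked features are native to boosted trees; other
    backends get a median-impute fallback."""
    if backend == "gbm":
        return X
    med = X.median()
    return X.fillna(med.fillna(0.0))


@dataclass
class TrainedSupportModel:
    model: object
    features: List[str]
    calibrators: List[IsotonicRegression]
    backend: str
    best_params: Dict
    metadata: Dict = field(default_factory=dict)

    def raw_scores(self, table: pd.DataFrame) -> np.ndarray:
        X, _ = _xy_nolabel(table, self.features)
        return self.model.predict_proba(_prep_X(X, self.backend))[:, 1]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedSupportModel":
        return joblib.load(path)


def _xy_nolabel(table: pd.DataFrame, features: Sequence[str]):
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise MLError(f"missing feature column(s): {missing}")
    return table[list(features)].astype(float).reset_index(drop=True), None


def _cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    params: Dict,
    config: ModelConfig,
    return_oof: bool = False,
):
    folds = group_kfold(groups, k=config.cv_folds, seed=config.seed)
    aucs = []
    oof = np.full(y.shape, np.nan)
    imps = []
    for tr, te in folds:
        est = _make_estimator(config.backend, params, config.seed)
        est.fit(_prep_X(X.iloc[tr], config.backend), y[tr])
        p = est.predict_proba(_prep_X(X.iloc[te], config.backend))[:, 1]
        oof[te] = p
        if np.unique(y[te]).size == 2:
            aucs.append(roc_auc_score(y[te], p))
        if config.backend == "gbm":
            imps.append(est.booster_.feature_importance(importance_type="gain"))
    mean_auc = float(np.mean(aucs)) if aucs else float("nan")
    mean_imp = np.mean(imps, axis=0) if imps else None
    if return_oof:
        return mean_auc, oof, mean_imp
    return mean_auc, mean_imp


def rfe_cv(
    table: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    config: Optional[ModelConfig] = None,
) -> List[str]:
    """Recursive feature elimination by information gain under grouped CV.

    Repeatedly drops the least-important feature while the cross-validated
    AUC does not decrease; stops at the first harmful removal.
    """
    config = config or ModelConfig()
    features = list(features or FEATURE_COLUMNS)
    if len(features) < 1:
        raise MLError("need at least one feature")
    X, y = _xy(table, features)
    groups = table["msa_id"].to_numpy()
    current = list(features)
    auc_cur, imp = _cv_auc(
        X[current], y, groups,
        _DEFAULT_PARAMS if config.backend == "gbm" else {}, config,
    )
    while len(current) > 1:
        if imp is None:
            break
        drop_i = int(np.argmin(imp))
        trial = [f for i, f in enumerate(current) if i != drop_i]
        auc_new, imp_new = _cv_auc(
            X[trial], y, groups,
            _DEFAULT_PARAMS if config.backend == "gbm" else {}, config,
        )
        if auc_new >= auc_cur - config.rfe_tol:
            current = trial
            auc_cur = auc_new
            imp = imp_new
        else:
            break
    return current


def tune_and_train(
    table: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    config: Optional[ModelConfig] = None,
) -> TrainedSupportModel:
    """Grid search by grouped CV on AUC, refit on the full training data,
    then isotonic calibration from grouped out-of-fold predictions."""
    config = config or ModelConfig()
    features = list(features or FEATURE_COLUMNS)
    if config.run_rfe:
        features = rfe_cv(table, features, config)
    X, y = _xy(table, features)
    if np.unique(y).size < 2:
        raise MLError("degenerate labels: a single class in the training data")
    groups = table["msa_id"].to_numpy()

    results = []
    best = None
    for params in config.sampled_grid():
        auc, _ = _cv_auc(X, y, groups, params, config)
        results.append({"params": params, "cv_auc": auc})
        if best is None or auc > best[0]:
            best = (auc, params)
    best_auc, best_params = best

    model = _make_estimator(config.backend, best_params, config.seed)
    model.fit(_prep_X(X, config.backend), y)

    # per-fold isotonic calibrators from out-of-fold raw predictions
    folds = group_kfold(groups, k=config.cv_folds, seed=config.seed)
    calibrators = []
    for tr, te in folds:
        est = _make_estimator(config.backend, best_params, config.seed)
        est.fit(_prep_X(X.iloc[tr], config.backend), y[tr])
        p = est.predict_proba(_prep_X(X.iloc[te], config.backend))[:, 1]
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(p, y[te])
        calibrators.append(iso)

    return TrainedSupportModel(
        model=model,
        features=features,
        calibrators=calibrators,
        backend=config.backend,
        best_params=best_params,
        metadata={
            "cv_results": results,
            "cv_auc_best": best_auc,
            "seed": config.seed,
            "n_train_rows": int(len(y)),
            "n_train_groups": int(np.unique(groups).size),
        },
    )


def predict_support(model: TrainedSupportModel, table: pd.DataFrame) -> np.ndarray:
    """Calibrated branch-support probabilities in [0, 1]; monotone in the
    raw ensemble score."""
    raw = model.raw_scores(table)
    cal = np.mean([iso.predict(raw) for iso in model.calibrators], axis=0)
    return np.clip(cal, 0.0, 1.0)


@dataclass
class FeatureImportanceReport:
    table: pd.DataFrame  # feature, gain_importance, single_feature_auc


def feature_importance(
    model: TrainedSupportModel,
    table: pd.DataFrame,
    config: Optional[ModelConfig] = None,
    single_feature_auc: bool = True,
) -> FeatureImportanceReport:
    """Information-gain importances of the fitted ensemble plus the CV AUC
    of a classifier refit on each feature alone."""
    config = config or ModelConfig(backend=model.backend)
    if model.backend == "gbm":
        gains = model.model.booster_.feature_importance(importance_type="gain")
    else:
        gains = getattr(model.model, "feature_importances_", np.zeros(len(model.features)))
    rows = []
    X, y = _xy(table, model.features)
    groups = table["msa_id"].to_numpy()
    for i, f in enumerate(model.features):
        sf_auc = np.nan
        if single_feature_auc:
            sf_auc, _ = _cv_auc(
                X[[f]], y, groups,
                _DEFAULT_PARAMS if config.backend == "gbm" else {}, config
            )
        rows.append(
            {"feature": f, "gain_importance": float(gains[i]), "single_feature_auc": sf_auc}
        )
    df = pd.DataFrame(rows).sort_values("gain_importance", ascending=False)
    return FeatureImportanceReport(table=df.reset_index(drop=True))
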