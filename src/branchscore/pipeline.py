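"""End-to-end pipelines: simulate -> infer -> featurize -> train -> score.

The main experiment mirrors the study design at desk scale: simulate
alignments, infer an ML tree for each with the internal search, extract
per-bipartition features, label them against the generating tree, split
70/30 by alignment with sequence-count stratification, tune and calibrate
the boosted-tree classifier on the training side, and evaluate on the
held-out side.  A validation batch on fresh trees supports the
calibration check and the model-misspecification scenarios (simulate
under JC / analyze under GTR and vice versa, on the same trees as the
matched-model control).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import DatasetSplit, label_bipartitions, stratified_group_split
from .evaluation import EvaluationReport, evaluate_scores
from .features import FEATURE_COLUMNS, compute_features
from .inference import LikelihoodEngine, ml_search, parsimony_tree_sample
from .ml import ModelConfig, TrainedSupportModel, predict_support, tune_and_train
from .phylo import Tree
from .seqsim import (
    MSA,
    SimulationConfig,
    SubstitutionModel,
    SimulatedReplicate,
    generate_dataset,
    simulate_msa,
)


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    ml: ModelConfig = field(default_factory=ModelConfig)
    n_msas: int = 550
    n_parsimony_trees: int = 25
    n_starts: int = 3
    seed: int = 0
    misspecification: Optional[str] = None  # None | jc-sim-gtr-fit | gtr-sim-jc-fit


def process_replicate(
    msa: MSA,
    true_tree: Tree,
    fit_model: SubstitutionModel,
    seed: int,
    msa_id: str,
    n_starts: int = 3,
    n_parsimony_trees: int = 25,
) -> pd.DataFrame:
    """Infer, featurize, and label one alignment.

    The fit model (used for likelihoods) may differ from the model the
    data were simulated under, which is how misspecification scenarios
    are expressed.
    """
    ss = np.random.SeedSequence(seed)
    s_search, s_pars = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    engine = LikelihoodEngine(msa, fit_model)
    result = ml_search(msa, fit_model, n_starts=n_starts, seed=s_search, engine=engine)
    ptrees = parsimony_tree_sample(msa, n_parsimony_trees, s_pars, engine=engine)
    df = compute_features(
        msa, result, ptrees, fit_model, engine=engine, msa_id=msa_id
    )
    df["label"] = label_bipartitions(result.best_tree, true_tree)
    return df


def build_feature_table(
    reps: Sequence[SimulatedReplicate],
    seed: int,
    n_starts: int = 3,
    n_parsimony_trees: int = 25,
    fit_model_fn: Optional[Callable[[SimulatedReplicate], SubstitutionModel]] = None,
    msa_fn: Optional[Callable[[SimulatedReplicate], MSA]] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> pd.DataFrame:
    """Feature+label rows for a batch of replicates.

    ``fit_model_fn`` / ``msa_fn`` override the analysis model or the
    alignment per replicate (misspecification designs); defaults use the
    simulation model and alignment unchanged.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(reps))]
    frames = []
    for i, rep in enumerate(reps):
        fit_model = fit_model_fn(rep) if fit_model_fn else rep.model
        msa = msa_fn(rep) if msa_fn else rep.msa
        frames.append(
            process_replicate(
                msa,
                rep.tree,
                fit_model,
                seeds[i],
                msa_id=rep.rep_id,
                n_starts=n_starts,
                n_parsimony_trees=n_parsimony_trees,
            )
        )
        if progress:
            progress(i + 1, len(reps))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    split: DatasetSplit
    model: TrainedSupportModel
    test_scores: np.ndarray
    report: EvaluationReport
    single_feature: Dict[str, object] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)


def run_experiment(
    config: PipelineConfig,
    single_feature: Optional[str] = "nni_ll_diff_min",
    progress: Optional[Callable[[int, int], None]] = None,
) -> ExperimentResult:
    """The full train/test experiment at the configured scale."""
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    s_data, s_table, s_split = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    )
    reps = generate_dataset(config.n_msas, config.sim, s_data)
    t1 = time.time()
    table = build_feature_table(
        reps,
        s_table,
        n_starts=config.n_starts,
        n_parsimony_trees=config.n_parsimony_trees,
        progress=progress,
    )
    t2 = time.time()
    split = stratified_group_split(table, train_frac=0.7, n_bins=5, seed=s_split)
    model = tune_and_train(split.train, FEATURE_COLUMNS, config.ml)
    scores = predict_support(model, split.test)
    report = evaluate_scores(
        scores,
        split.test["label"].to_numpy(),
        groups=split.test["msa_id"].to_numpy(),
    )
    t3 = time.time()
    sf: Dict[str, object] = {}
    if single_feature:
        sf_model = tune_and_train(split.train, [single_feature], config.ml)
        sf_scores = predict_support(sf_model, split.test)
        sf_report = evaluate_scores(sf_scores, split.test["label"].to_numpy())
        sf = {"feature": single_feature, "model": sf_model, "report": sf_report}
    t4 = time.time()
    return ExperimentResult(
        table=table,
        split=split,
        model=model,
        test_scores=scores,
        report=report,
        single_feature=sf,
        timings={
            "simulate": t1 - t0,
            "featurize": t2 - t1,
            "train_eval": t3 - t2,
            "single_feature": t4 - t3,
        },
    )


# ---------------------------------------------------------------------------
# validation batches (calibration + misspecification)
# ---------------------------------------------------------------------------


def build_validation_tables(
    config: PipelineConfig,
    seed: int,
    n_control: int,
    n_misspec: int = 0,
    min_control_rows: Optional[int] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> Dict[str, pd.DataFrame]:
    """Independent validation batches on fresh trees.

    ``control``: matched generating/fitting models.  If ``n_misspec`` > 0
    the first ``n_misspec`` trees additionally yield ``jc_sim_gtr_fit``
    (data re-simulated under plain JC on the same tree, analyzed under
    the drawn GTR+Gamma model) and ``gtr_sim_jc_fit`` (the control
    alignment analyzed under JC exchangeabilities and frequencies while
    keeping the rate-heterogeneity model, the analog of a JC+CAT
    analysis), mirroring the misspecification design on shared trees.
    """
    ss = np.random.SeedSequence(seed)
    s_data, s_control, s_jc, s_gtr = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    )
    reps = generate_dataset(n_control, config.sim, s_data)
    out: Dict[str, pd.DataFrame] = {}
    control = build_feature_table(
        reps,
        s_control,
        n_starts=config.n_starts,
        n_parsimony_trees=config.n_parsimony_trees,
        progress=progress,
    )
    # top up with extra replicates until the requested row count is met
    chunk = 0
    while min_control_rows is not None and len(control) < min_control_rows:
        chunk += 1
        extra_reps = generate_dataset(
            40, config.sim, (s_data + chunk) % (2**31 - 1)
        )
        for r in extra_reps:
            r.rep_id = f"extra{chunk:02d}_{r.rep_id}"
        extra = build_feature_table(
            extra_reps,
            (s_control + chunk) % (2**31 - 1),
            n_starts=config.n_starts,
            n_parsimony_trees=config.n_parsimony_trees,
            progress=progress,
        )
        control = pd.concat([control, extra], ignore_index=True)
    out["control"] = control
    if n_misspec > 0:
        sub = reps[:n_misspec]
        jc = SubstitutionModel.jc()
        out["jc_sim_gtr_fit"] = build_feature_table(
            sub,
            s_jc,
            n_starts=config.n_starts,
            n_parsimony_trees=config.n_parsimony_trees,
            msa_fn=lambda r: simulate_msa(r.tree, jc, r.msa.n_sites, r.seed),
            progress=progress,
        )
        def _jc_with_rates(r: SimulatedReplicate) -> SubstitutionModel:
            return SubstitutionModel(
                rates=np.ones(6),
                freqs=np.full(4, 0.25),
                alpha=r.model.alpha,
                pinv=r.model.pinv,
                ncat=r.model.ncat,
            )

        out["gtr_sim_jc_fit"] = build_feature_table(
            sub,
            s_gtr,
            n_starts=config.n_starts,
            n_parsimony_trees=config.n_parsimony_trees,
            fit_model_fn=_jc_with_rates,
            progress=progress,
        )
        out["control_misspec_subset"] = out["control"][
            out["control"]["msa_id"].isin({r.rep_id for r in sub})
        ].reset_index(drop=True)
    return out


def score_table(model: TrainedSupportModel, table: pd.DataFrame) -> EvaluationReport:
    scores = predict_support(model, table)
    return evaluate_scores(
        scores, table["label"].to_numpy(), groups=table["msa_id"].to_numpy()
    )
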