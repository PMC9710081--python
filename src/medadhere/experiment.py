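"""End-to-end experiment orchestration.

Ties the pieces together the way the study protocol prescribes: simulate
(or load) a cohort, apply the exclusion cascade, build the quarterly
feature tensor, split into a held-out test set plus five rotated 90/10
train/validation folds, train every model on the fold-1 training split
with training-split-only feature scaling, and compare test-set scores.

Also implements the post-index window-length experiment: with the end of
prediction quarter 16 as a new index date, predict adherence over quarters
17–20 from 4/8/12/16 quarters of history, after removing patients who died
before the new index.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .estimators import (
    LSTMAdherenceClassifier,
    LogisticAdherenceClassifier,
    MLPAdherenceClassifier,
    RidgeAdherenceClassifier,
    SimpleRNNAdherenceClassifier,
    SplitScheme,
)
from .evaluation import ScoredTestSet, compare_models
from .pipeline import (
    FeatureScaler,
    QuarterGrid,
    apply_exclusions,
    build_feature_tensor,
    make_model_inputs,
)
from .simulate import Cohort, SimulationConfig, simulate_cohort

#: Reference training-set size the published batch sizes were tuned on;
#: desk-scale runs shrink batches proportionally (floor 32).
REFERENCE_TRAIN_SIZE = 81000


@dataclass(frozen=True)
class ModelSpec:
    """A model family paired with the input variant it consumes."""

    name: str
    family: str       # lstm | rnn | mlp | ridge | logistic
    variant: str      # sequential | flattened | aggregated | last_quarter
    overrides: dict = field(default_factory=dict)


DEFAULT_MODELS = (
    ModelSpec("LSTM", "lstm", "sequential"),
    ModelSpec("Simple RNN", "rnn", "sequential"),
    ModelSpec("MLP", "mlp", "flattened"),
    ModelSpec("RC", "ridge", "flattened"),
    ModelSpec("RC (aggregated)", "ridge", "aggregated"),
    ModelSpec("RC (last quarter)", "ridge", "last_quarter"),
    ModelSpec("LR", "logistic", "flattened"),
    ModelSpec("LR (aggregated)", "logistic", "aggregated"),
    ModelSpec("LR (last quarter)", "logistic", "last_quarter"),
)


def _desk_batch(paper_batch: int, n_train: int) -> int:
    return int(max(32, min(paper_batch,
                           round(paper_batch * n_train / REFERENCE_TRAIN_SIZE))))


def build_estimator(spec: ModelSpec, n_train: int, seed: int):
    o = dict(spec.overrides)
    if spec.family == "lstm":
        return LSTMAdherenceClassifier(
            units=o.get("units", 4), l2=o.get("l2", 9.261e-3),
            batch_size=o.get("batch_size", _desk_batch(1024, n_train)),
            epochs=o.get("epochs", 100), seed=seed)
    if spec.family == "rnn":
        return SimpleRNNAdherenceClassifier(
            units=o.get("units", 8), l2=o.get("l2", 1.202e-2),
            batch_size=o.get("batch_size", _desk_batch(4096, n_train)),
            epochs=o.get("epochs", 100), seed=seed)
    if spec.family == "mlp":
        return MLPAdherenceClassifier(
            hidden=o.get("hidden", (64, 64)),
            dropout=o.get("dropout", (0.2152, 0.1758)),
            batch_size=o.get("batch_size", _desk_batch(256, n_train)),
            epochs=o.get("epochs", 50), seed=seed)
    if spec.family == "ridge":
        return RidgeAdherenceClassifier(seed=seed)
    if spec.family == "logistic":
        return LogisticAdherenceClassifier(seed=seed)
    raise ValueError(f"unknown model family {spec.family!r}")


def train_model(spec: ModelSpec, tensor, splits: dict, seed: int):
    """Train one model on the fold-1 training split; return (est, scores)."""
    X, y = make_model_inputs(tensor, spec.variant)
    train_idx, _val_idx = splits["folds"][0]
    test_idx = splits["test"]
    scaler = FeatureScaler.for_variant(tensor, spec.variant)
    scaler.fit(X[train_idx])
    Xs = scaler.transform(X)
    est = build_estimator(spec, len(train_idx), seed)
    est.fit(Xs[train_idx], y[train_idx])
    return est, est.decision_function(Xs[test_idx])


@dataclass
class ExperimentResult:
    scored: ScoredTestSet
    report: object              # ComparisonReport
    exclusion_report: object
    n_patients: int
    n_test: int

    def to_json_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_test": self.n_test,
            "exclusions": [list(r) for r in self.exclusion_report.rows],
            "comparison": self.report.to_json_dict(),
        }


def run_adherence_experiment(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    models: Sequence[ModelSpec] = DEFAULT_MODELS,
    scheme: Optional[SplitScheme] = None,
    cohort: Optional[Cohort] = None,
    alpha: float = 0.05,
) -> ExperimentResult:
    """Full pipeline on a (simulated) cohort; deterministic in (config, seed)."""
    config = config or SimulationConfig()
    if cohort is None:
        cohort = simulate_cohort(config, seed)
    grid = QuarterGrid(index_date=config.index_day,
                       n_obs_quarters=config.n_obs_quarters,
                       n_pred_quarters=config.n_pred_quarters,
                       quarter_length=config.quarter_length)
    filtered, excl_report = apply_exclusions(cohort, grid)
    tensor = build_feature_tensor(filtered, grid)
    scheme = scheme or SplitScheme()
    splits = scheme.split(len(tensor.patient_ids), seed)
    test_idx = splits["test"]
    scores = {}
    for spec in models:
        _, s = train_model(spec, tensor, splits, seed)
        scores[spec.name] = s
    scored = ScoredTestSet(
        labels=tensor.labels[test_idx], scores=scores,
        patient_ids=[tensor.patient_ids[i] for i in test_idx])
    report = compare_models(scored, alpha=alpha)
    return ExperimentResult(scored=scored, report=report,
                            exclusion_report=excl_report,
                            n_patients=len(tensor.patient_ids),
                            n_test=len(test_idx))


# ---------------------------------------------------------------------------
# post-index window-length experiment
# ---------------------------------------------------------------------------

POST_WINDOW_LENGTHS = (4, 8, 12, 16)

POST_DEFAULT_MODELS = (
    ModelSpec("LSTM", "lstm", "sequential"),
    ModelSpec("Simple RNN", "rnn", "sequential"),
    ModelSpec("MLP", "mlp", "flattened"),
    ModelSpec("RC", "ridge", "flattened"),
    ModelSpec("RC (aggregated)", "ridge", "aggregated"),
)


def post_predict_experiment(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    window_lengths: Sequence[int] = POST_WINDOW_LENGTHS,
    models: Sequence[ModelSpec] = POST_DEFAULT_MODELS,
    scheme: Optional[SplitScheme] = None,
    cohort: Optional[Cohort] = None,
    alpha: float = 0.05,
) -> dict:
    """Window-length study: predict quarters 17–20 from L quarters of history.

    The new index date is the end of prediction quarter 16.  Patients who
    died before it are removed.  For each L the observation window is
    quarters (17-L)..16, models are retrained from scratch, and a
    comparison report is produced.  Returns {L: ExperimentResult-like dict}.
    """
    config = config or SimulationConfig(long_memory=True)
    for L in window_lengths:
        if not 1 <= L <= 16:
            raise ValueError(f"window length {L} outside 1..16")
    if cohort is None:
        cohort = simulate_cohort(config, seed)
    new_offset = 16 * config.quarter_length
    kept = [p for p in cohort.profiles
            if p.death_date is None
            or p.death_date >= p.index_date + new_offset]
    ids = {p.patient_id for p in kept}
    base = Cohort(
        profiles=kept,
        dispenses=[e for e in cohort.dispenses if e.patient_id in ids],
        labs=[r for r in cohort.labs if r.patient_id in ids],
        hospital_events=[h for h in cohort.hospital_events
                         if h.patient_id in ids],
        ground_truth={k: v for k, v in cohort.ground_truth.items()
                      if k in ids},
        config=cohort.config, seed=cohort.seed)
    # shift every patient's index to the new one
    base.profiles = [dataclasses.replace(p, index_date=p.index_date + new_offset)
                     for p in base.profiles]

    scheme = scheme or SplitScheme()
    results = {}
    for L in window_lengths:
        grid = QuarterGrid(index_date=config.index_day + new_offset,
                           n_obs_quarters=L, n_pred_quarters=4,
                           quarter_length=config.quarter_length)
        tensor = build_feature_tensor(base, grid)
        splits = scheme.split(len(tensor.patient_ids), seed)
        test_idx = splits["test"]
        scores = {}
        for spec in models:
            _, s = train_model(spec, tensor, splits, seed)
            scores[spec.name] = s
        scored = ScoredTestSet(labels=tensor.labels[test_idx], scores=scores)
        report = compare_models(scored, alpha=alpha)
        results[L] = {
            "n_patients": len(tensor.patient_ids),
            "auc": report.auc,
            "report": report,
        }
    return results
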