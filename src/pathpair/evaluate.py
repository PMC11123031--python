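"""Tuning, Monte-Carlo cross-validation, metrics and importance aggregation.

Evaluation is Monte-Carlo CV: each iteration draws an independent stratified
train/test split, duplicates the positive training rows to balance classes,
fits a fresh classifier and scores the untouched test rows.  The headline
metric is the Matthews correlation coefficient (MCC), computed from the full
confusion matrix and defined as 0 whenever a factor of its denominator is 0.

Hyperparameter search is a seeded random search: each trial samples one
configuration, runs up to ``cv_per_trial`` sequential CV iterations and may
be pruned early by a median-stopping rule; the objective is the median MCC
across a trial's iterations.

Feature importance (tree backend only) is aggregated across iterations:
within each iteration a softmax over the raw gain scores of the retained
features yields relative importances summing to 1; these are averaged across
iterations and ranked.  Features whose gain is 0 in every iteration are
excluded before the softmax, so they carry exactly 0 relative importance.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AggregationError,
    InsufficientPairsError,
    ShapeError,
    TuningError,
    ValidationError,
)
from .io import OVERALL, ResultsStore
from .matrix import METABOLITE, PATHWAY
from .models import (
    GBT,
    ClassifierSpec,
    predict,
    raw_feature_importance,
    train_classifier,
)
from .pairs import PairDataset, SplitPlan, atom_color_of, oversample_positives, stratified_split

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, precision, recall, F1 and MCC for one test set."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def compute_metrics(predicted: Sequence[int], truth: Sequence[int]) -> MetricSet:
    """Confusion-matrix metrics with the zero-denominator-is-zero convention.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any factor
    of the denominator is 0 the MCC is defined as 0.  Precision, recall and
    F1 likewise fall back to 0 on a zero denominator.
    """
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ShapeError("predicted and truth must be equal-length 1-D sequences")
    if predicted.size == 0:
        raise ValidationError("cannot score an empty prediction set")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / float(np.sqrt(denom2)) if denom2 else 0.0
    return MetricSet(accuracy, precision, recall, f1, mcc)


@dataclass
class CvRecord:
    """One CV iteration: overall metrics, per-pathway MCC, optional importances."""

    iteration: int
    metrics: MetricSet
    per_pathway_mcc: dict[str, float]
    importance: dict[str, float] | None = None
    error: str | None = None


def run_cv(
    spec: ClassifierSpec,
    ds: PairDataset,
    n_iterations: int,
    plan: SplitPlan,
    store: ResultsStore | None = None,
    feature_set: str = "non-encoded",
    collect_importance: bool = False,
) -> list[CvRecord]:
    """Monte-Carlo CV: split, oversample train, fit, score the clean test set.

    Iteration ``i`` uses split seed ``plan.seed + i`` and classifier seed
    ``spec.seed + i``, so iterations are independent of execution order and a
    run can be resumed or parallelized without a shared random stream.  Test
    sets are never oversampled.  A failing iteration is recorded and skipped;
    the remaining iterations continue.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if collect_importance and spec.kind != GBT:
        raise ValidationError("importance collection requires the gbt backend")
    records: list[CvRecord] = []
    for i in range(n_iterations):
        try:
            records.append(
                _one_cv_iteration(spec, ds, plan, i, collect_importance)
            )
        except Exception as exc:  # noqa: BLE001 - surfaced, not swallowed
            logger.error("CV iteration %d failed: %s", i, exc)
            records.append(
                CvRecord(i, MetricSet(0, 0, 0, 0, 0), {}, error=str(exc))
            )
            continue
        if store is not None:
            rec = records[-1]
            for metric_name, value in rec.metrics.as_dict().items():
                store.record_cv_metric(
                    spec.kind, feature_set, i, OVERALL, metric_name, value
                )
            for pathway, value in rec.per_pathway_mcc.items():
                store.record_cv_metric(
                    spec.kind, feature_set, i, pathway, "mcc", value
                )
    return records


def _one_cv_iteration(
    spec: ClassifierSpec,
    ds: PairDataset,
    plan: SplitPlan,
    iteration: int,
    collect_importance: bool,
) -> CvRecord:
    split_plan = SplitPlan(plan.test_fraction, plan.seed + iteration)
    train, test = stratified_split(ds, split_plan)
    train = oversample_positives(train)
    clf = train_classifier(spec.with_seed(spec.seed + iteration), train)
    _, predicted = predict(clf, test)
    metrics = compute_metrics(predicted, test.labels)
    per_pathway: dict[str, float] = {}
    for p, pname in enumerate(ds.pathways.entry_ids):
        mask = test.path_idx == p
        if mask.any():
            per_pathway[pname] = compute_metrics(
                predicted[mask], test.labels[mask]
            ).mcc
    importance = raw_feature_importance(clf) if collect_importance else None
    return CvRecord(iteration, metrics, per_pathway, importance)


def summarize_records(records: list[CvRecord]) -> pd.DataFrame:
    """Mean/std of each overall metric across successful iterations."""
    ok = [r for r in records if r.error is None]
    if not ok:
        raise ValidationError("no successful CV iterations to summarize")
    frame = pd.DataFrame([r.metrics.as_dict() for r in ok])
    return frame.agg(["mean", "std"])


def per_pathway_summary(records: list[CvRecord]) -> pd.DataFrame:
    """Per-pathway mean/std MCC across successful iterations."""
    ok = [r for r in records if r.error is None]
    frame = pd.DataFrame([r.per_pathway_mcc for r in ok])
    out = pd.DataFrame({"mean_mcc": frame.mean(), "std_mcc": frame.std()})
    out.index.name = "pathway"
    return out


# ---------------------------------------------------------------------------
# Hyperparameter search

GBT_SPACE: dict[str, dict[str, Any]] = {
    "n_estimators": {"type": "int", "low": 50, "high": 500},
    "max_depth": {"type": "int", "low": 2, "high": 10},
    "learning_rate": {"type": "float", "low": 0.01, "high": 0.3, "log": True},
    "subsample": {"type": "float", "low": 0.5, "high": 1.0},
    "colsample_bytree": {"type": "float", "low": 0.5, "high": 1.0},
    "min_child_weight": {"type": "int", "low": 1, "high": 10},
}
MLP_SPACE: dict[str, dict[str, Any]] = {
    "hidden_layer_sizes": {
        "type": "categorical",
        "choices": [(32,), (64,), (64, 32), (128, 64)],
    },
    "alpha": {"type": "float", "low": 1e-6, "high": 1e-2, "log": True},
    "learning_rate_init": {"type": "float", "low": 1e-4, "high": 1e-2, "log": True},
    "batch_size": {"type": "categorical", "choices": [64, 128, 256]},
    "max_epochs": {"type": "int", "low": 100, "high": 400},
    "patience": {"type": "int", "low": 10, "high": 30},
}


def _sample_params(space: dict[str, dict], rng: np.random.Generator) -> dict:
    params: dict[str, Any] = {}
    for name, desc in space.items():
        kind = desc.get("type", "float")
        if kind == "categorical":
            params[name] = desc["choices"][rng.integers(len(desc["choices"]))]
        elif kind == "int":
            params[name] = int(rng.integers(desc["low"], desc["high"] + 1))
        else:
            lo, hi = float(desc["low"]), float(desc["high"])
            if desc.get("log"):
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[name] = float(rng.uniform(lo, hi))
    return params


@dataclass
class TrialRecord:
    """One search trial: sampled params, its MCC trajectory, prune status."""

    trial_id: int
    params: dict[str, Any]
    mccs: list[float] = field(default_factory=list)
    pruned: bool = False

    @property
    def median_mcc(self) -> float | None:
        # median of an even count = mean of the two central values
        return statistics.median(self.mccs) if self.mccs else None

    def running_medians(self) -> list[float]:
        return [statistics.median(self.mccs[: s + 1]) for s in range(len(self.mccs))]


def tune(
    spec_space: dict[str, dict[str, Any]],
    ds: PairDataset,
    kind: str = GBT,
    n_trials: int = 100,
    cv_per_trial: int = 20,
    store: ResultsStore | None = None,
    plan: SplitPlan | None = None,
    seed: int = 0,
    n_startup_trials: int = 1,
    n_warmup_steps: int = 1,
    study: str = "",
) -> dict[str, Any]:
    """Random-search tuning with median-rule pruning; returns the best params.

    Each trial runs up to ``cv_per_trial`` CV iterations; after each step the
    trial's running median MCC is compared against the median of the running
    medians that previously completed trials achieved at the same step, and
    the trial is pruned when it falls below (after ``n_warmup_steps`` steps,
    once ``n_startup_trials`` trials completed).  All trials share the same
    per-step split seeds so intermediate values are comparable.  The best
    trial maximizes the median MCC over its iterations.
    """
    if not spec_space:
        raise TuningError("empty search space")
    if plan is None:
        plan = SplitPlan(seed=seed)
    rng = np.random.default_rng(seed)
    completed: list[TrialRecord] = []
    all_trials: list[TrialRecord] = []
    for trial_id in range(n_trials):
        params = _sample_params(spec_space, rng)
        spec = ClassifierSpec(kind, params, seed=seed + 1000 * trial_id)
        trial = TrialRecord(trial_id, params)
        for step in range(cv_per_trial):
            step_plan = SplitPlan(plan.test_fraction, plan.seed + step)
            train, test = stratified_split(ds, step_plan)
            train = oversample_positives(train)
            clf = train_classifier(spec.with_seed(spec.seed + step), train)
            _, predicted = predict(clf, test)
            trial.mccs.append(compute_metrics(predicted, test.labels).mcc)
            if (
                step + 1 > n_warmup_steps
                and len(completed) >= n_startup_trials
                and _should_prune(trial, completed, step)
            ):
                trial.pruned = True
                break
        if not trial.pruned:
            completed.append(trial)
        all_trials.append(trial)
        if store is not None:
            store.record_trial(
                trial_id, params, trial.median_mcc, trial.pruned, study=study
            )
    scored = [t for t in all_trials if t.median_mcc is not None]
    if not scored:
        raise TuningError("all trials pruned before producing any MCC")
    best = max(scored, key=lambda t: (t.median_mcc, -t.trial_id))
    return dict(best.params)


def _should_prune(
    trial: TrialRecord, completed: list[TrialRecord], step: int
) -> bool:
    peers = [
        t.running_medians()[step] for t in completed if len(t.mccs) > step
    ]
    if not peers:
        return False
    return trial.running_medians()[step] < statistics.median(peers)


# ---------------------------------------------------------------------------
# Importance aggregation


@dataclass
class ImportanceTable:
    """Ranked mean relative importances with metabolite/pathway cross-links.

    ``table`` columns: feature_name, entity_kind, atom_color,
    mean_relative_importance, rank, counterpart_rank (rank of the same atom
    color on the other entity kind, NaN when absent).
    """

    table: pd.DataFrame
    per_iteration_relative: pd.DataFrame  # iterations x retained features


def aggregate_importance(
    per_iteration: list[dict[str, float]]
) -> ImportanceTable:
    """Softmax raw gain scores within each iteration, then average and rank.

    Features scoring 0 in every iteration are dropped before the softmax, so
    the retained features' relative importances sum to 1 within each
    iteration.  A feature missing from one iteration's map is treated as raw
    0 in that iteration (but still retained if it ever scored).
    """
    if not per_iteration:
        raise AggregationError("no importance maps to aggregate")
    names = sorted(set().union(*per_iteration))
    raw = np.zeros((len(per_iteration), len(names)))
    for i, scores in enumerate(per_iteration):
        for j, name in enumerate(names):
            raw[i, j] = scores.get(name, 0.0)
    ever_nonzero = (raw != 0).any(axis=0)
    kept = [n for n, keep in zip(names, ever_nonzero) if keep]
    if not kept:
        raise AggregationError("every feature scored 0 in every iteration")
    block = raw[:, ever_nonzero]
    shifted = block - block.max(axis=1, keepdims=True)  # numerically safe softmax
    expd = np.exp(shifted)
    relative = expd / expd.sum(axis=1, keepdims=True)
    mean_rel = relative.mean(axis=0)
    rows = []
    for name, score in zip(kept, mean_rel):
        color = atom_color_of(name)
        if name.startswith("pathway::"):
            kind = PATHWAY
        elif name.startswith("metabolite::"):
            kind = METABOLITE
        else:
            kind, color = "unknown", name
        rows.append(
            {
                "feature_name": name,
                "entity_kind": kind,
                "atom_color": color,
                "mean_relative_importance": score,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mean_relative_importance", "feature_name"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    rank_by_key = {
        (r.entity_kind, r.atom_color): r.rank for r in table.itertuples()
    }
    other = {METABOLITE: PATHWAY, PATHWAY: METABOLITE}
    table["counterpart_rank"] = [
        rank_by_key.get((other.get(r.entity_kind, ""), r.atom_color), np.nan)
        for r in table.itertuples()
    ]
    per_iter = pd.DataFrame(relative, columns=kept)
    return ImportanceTable(table=table, per_iteration_relative=per_iter)


def importance_correlation(
    table: ImportanceTable,
) -> tuple[float, float, int]:
    """Pearson/Spearman correlation of paired metabolite vs pathway importances.

    Pairs are atom colors whose importance survived aggregation on both
    entity kinds; colors excluded on either side (all-zero gain or
    de-duplicated away) are dropped.  With a constant side, Pearson is
    undefined and reported as NaN with a warning.
    """
    t = table.table
    met = t[t.entity_kind == METABOLITE].set_index("atom_color")[
        "mean_relative_importance"
    ]
    path = t[t.entity_kind == PATHWAY].set_index("atom_color")[
        "mean_relative_importance"
    ]
    shared = met.index.intersection(path.index)
    n_pairs = len(shared)
    if n_pairs < 3:
        raise InsufficientPairsError(
            f"need >= 3 atom colors important on both sides, found {n_pairs}"
        )
    x, y = met.loc[shared].to_numpy(), path.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant importance vector: Pearson correlation undefined")
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman, n_pairs


def record_importance_iterations(
    store: ResultsStore, table: ImportanceTable, raw_iterations: list[dict[str, float]]
) -> None:
    """Persist per-iteration raw and relative scores for the retained features."""
    kept = list(table.per_iteration_relative.columns)
    kinds = dict(zip(table.table.feature_name, table.table.entity_kind))
    for i, raw in enumerate(raw_iterations):
        rel = table.per_iteration_relative.iloc[i]
        for name in kept:
            store.record_importance(
                name, kinds.get(name, "unknown"), i, raw.get(name, 0.0), float(rel[name])
            )
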