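"""Classifier backends behind one train/predict contract.

Two backends: gradient-boosted trees (XGBoost) and a multilayer perceptron
(scikit-learn).  Class imbalance is handled upstream by duplicating positive
training rows, so neither backend re-weights its loss.  Gain-based feature
importance is defined only for the tree backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .errors import BalanceError, ShapeError, UnsupportedModelError, ValidationError
from .pairs import PairDataset

GBT = "gbt"
MLP = "mlp"

# Shipped defaults are midpoints of the tuning search space (see evaluate);
# tune() is the intended way to pick real values for a new dataset.
DEFAULT_GBT_PARAMS: dict[str, Any] = {
    "n_estimators": 200,
    "max_depth": 6,
    "learning_rate": 0.1,
    "subsample": 0.75,
    "colsample_bytree": 0.75,
    "min_child_weight": 5,
}
DEFAULT_MLP_PARAMS: dict[str, Any] = {
    "hidden_layer_sizes": (64, 32),
    "alpha": 1e-4,
    "learning_rate_init": 1e-3,
    "batch_size": 128,
    "max_epochs": 300,
    "patience": 20,
    "early_stopping": True,
}


@dataclass
class ClassifierSpec:
    """Backend choice, hyperparameters and seed."""

    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (GBT, MLP):
            raise ValidationError(f"kind must be '{GBT}' or '{MLP}', got {self.kind!r}")
        defaults = DEFAULT_GBT_PARAMS if self.kind == GBT else DEFAULT_MLP_PARAMS
        merged = dict(defaults)
        unknown = set(self.hyperparameters) - set(defaults)
        if unknown:
            raise ValidationError(f"unknown {self.kind} hyperparameters: {sorted(unknown)}")
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(self.kind, dict(self.hyperparameters), seed)


@dataclass
class TrainedClassifier:
    kind: str
    model: Any
    feature_names: list[str]


def _build_estimator(spec: ClassifierSpec):
    p = spec.hyperparameters
    if spec.kind == GBT:
        return XGBClassifier(
            n_estimators=int(p["n_estimators"]),
            max_depth=int(p["max_depth"]),
            learning_rate=float(p["learning_rate"]),
            subsample=float(p["subsample"]),
            colsample_bytree=float(p["colsample_bytree"]),
            min_child_weight=float(p["min_child_weight"]),
            tree_method="hist",
            eval_metric="logloss",
            random_state=spec.seed,
            n_jobs=1,
        )
    hidden = tuple(int(h) for h in p["hidden_layer_sizes"])
    return MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        alpha=float(p["alpha"]),
        learning_rate_init=float(p["learning_rate_init"]),
        batch_size=int(p["batch_size"]),
        max_iter=int(p["max_epochs"]),
        early_stopping=bool(p["early_stopping"]),
        validation_fraction=0.1,
        n_iter_no_change=int(p["patience"]),
        random_state=spec.seed,
    )


def train_classifier(spec: ClassifierSpec, train: PairDataset) -> TrainedClassifier:
    """Fit one backend on a (typically oversampled) training pair set."""
    y = train.labels.astype(np.int64)
    if train.n_rows == 0 or len(np.unique(y)) < 2:
        raise BalanceError("training set must contain both classes")
    x = train.features()
    est = _build_estimator(spec)
    est.fit(x, y)
    return TrainedClassifier(kind=spec.kind, model=est, feature_names=train.feature_names)


def _check_width(clf: TrainedClassifier, rows: PairDataset) -> None:
    if rows.feature_names != clf.feature_names:
        raise ShapeError(
            f"prediction input width/ordering ({rows.width}) does not match the "
            f"classifier's training columns ({len(clf.feature_names)})"
        )


def predict(
    clf: TrainedClassifier, rows: PairDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Scores in [0, 1] and hard labels at threshold 0.5, in input row order."""
    _check_width(clf, rows)
    if rows.n_rows == 0:
        return np.empty(0), np.empty(0, dtype=np.int8)
    scores = clf.model.predict_proba(rows.features())[:, 1]
    labels = (scores >= 0.5).astype(np.int8)
    return scores, labels


def raw_feature_importance(clf: TrainedClassifier) -> dict[str, float]:
    """Gain importance per feature for the tree backend.

    Gain is the total training-loss reduction contributed by splits on the
    feature; features never used by any split score exactly 0.  Every input
    feature is present in the returned map.
    """
    if clf.kind != GBT:
        raise UnsupportedModelError(
            "feature importance is defined only for the gradient-boosted tree backend"
        )
    booster = clf.model.get_booster()
    raw = booster.get_score(importance_type="gain")
    scores = dict.fromkeys(clf.feature_names, 0.0)
    for key, value in raw.items():
        # xgboost names features f0, f1, ... when fitted on a bare array
        name = clf.feature_names[int(key[1:])] if key.startswith("f") else key
        scores[name] = float(value)
    return scores
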