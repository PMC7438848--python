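"""Stratified splitting, random-forest classification, and evaluation.

The evaluation conventions: epileptiform discharge is the positive class;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/(TP+FP+TN+FN); the ROC sweeps the class-probability
threshold and the AUC equals the Mann-Whitney concordance probability.
Splits take exactly floor(2/3 * n) training items per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "stratified_split",
    "train_rf",
    "predict_scores",
    "confusion",
    "metrics",
    "roc_auc",
]

POSITIVE_LABEL = "discharge"


@dataclass
class ConfusionMatrix:
    """TP/FN/FP/TN counts with epileptiform discharge as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Fractions in [0, 1] plus the ROC curve as (FPR, TPR) pairs."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None
    roc: np.ndarray | None = None
    confusion: ConfusionMatrix | None = None


def stratified_split(
    labels: np.ndarray,
    train_frac: float = 2.0 / 3.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split with floor(train_frac * n_class) training items.

    Disjoint, exhaustive and seed-deterministic.  Any class with fewer than
    3 members raises (it could not contribute to both subsets reliably).
    """
    labels = np.asarray(labels)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has only {idx.size} members (< 3)")
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_frac * idx.size))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def train_rf(
    features: np.ndarray,
    labels: np.ndarray,
    n_estimators: int = 100,
    seed: int | None = None,
) -> RandomForestClassifier:
    """Fit a majority-vote random forest (impurity splits, unlimited depth)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain NaN or Inf")
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(features, labels)
    return model


def predict_scores(
    model: RandomForestClassifier,
    features: np.ndarray,
    positive_label=1,
) -> np.ndarray:
    """Probability of the positive class for each row of ``features``."""
    classes = list(model.classes_)
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} unknown to the model")
    proba = model.predict_proba(np.asarray(features, dtype=float))
    return proba[:, classes.index(positive_label)]


def confusion(pred_labels, true_labels, positive_label=1) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    pos_pred = pred == positive_label
    pos_true = true == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_pred & pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as fractions.

    A zero denominator raises rather than silently reporting 0.
    """
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive cases")
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative cases")
    if cm.total == 0:
        raise ZeroDivisionError("accuracy undefined: empty confusion matrix")
    return (
        cm.tp / (cm.tp + cm.fn),
        cm.tn / (cm.tn + cm.fp),
        (cm.tp + cm.tn) / cm.total,
    )


def roc_auc(scores, labels, positive_label=1) -> tuple[float, np.ndarray]:
    """Threshold-swept ROC curve and its trapezoidal area.

    Returns (auc, roc) where roc is an (n, 2) array of (FPR, TPR) pairs.
    The area equals the Mann-Whitney concordance probability with ties
    counted as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), scores)
    return float(_sk_auc(fpr, tpr)), np.column_stack([fpr, tpr])
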