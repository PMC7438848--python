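"""End-to-end orchestration: epochs -> features -> classifier -> report.

A master seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
so individual stages can be re-run independently while keeping the whole run
byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify
from .channels import CHANNELS
from .features import MethodOneFeaturizer
from .io import EegEpoch
from .localize import LocalizationConfig, cohort_localization, subject_localization
from .netsvd import MethodTwoFeaturizer, all_difference_networks
from .synth import TEMPLATE_KINDS

__all__ = [
    "RunConfig",
    "run_method_one",
    "run_method_two",
    "run_localization",
    "phase_diagram",
]


@dataclass
class RunConfig:
    """Parameters of one classification run."""

    method: str = "two"
    train_frac: float = 2.0 / 3.0
    seed: int = 0
    n_estimators: int = 100
    afa_order: int = 2
    relative_alpha: bool = True
    topk: int = 10
    decision_threshold: float = 0.5
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(2)
        return {
            "split": int(children[0].generate_state(1)[0] % (2**31 - 1)),
            "forest": int(children[1].generate_state(1)[0] % (2**31 - 1)),
        }


def _binary_labels(epochs: Sequence[EegEpoch]) -> np.ndarray:
    labels = []
    for e in epochs:
        if e.label is None:
            raise ValueError("all epochs must be labeled for a classification run")
        labels.append(0 if e.label == "normal" else 1)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes (normal and discharge) must be present")
    return y


def _run(epochs: Sequence[EegEpoch], config: RunConfig, featurizer, columns) -> tuple[pd.DataFrame, classify.MetricsReport]:
    y = _binary_labels(epochs)
    X = featurizer.fit_transform(list(epochs))
    if not np.all(np.isfinite(X)):
        raise ValueError("degenerate (non-finite) features; check the input epochs")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError(
            "degenerate features: every epoch maps to the same feature vector"
        )
    seeds = config.stage_seeds()
    train_idx, test_idx = classify.stratified_split(
        y, train_frac=config.train_frac, seed=seeds["split"]
    )
    model = classify.train_rf(
        X[train_idx], y[train_idx],
        n_estimators=config.n_estimators, seed=seeds["forest"],
    )
    scores = classify.predict_scores(model, X[test_idx], positive_label=1)
    pred = (scores >= config.decision_threshold).astype(int)
    cm = classify.confusion(pred, y[test_idx], positive_label=1)
    sens, spec, acc = classify.metrics(cm)
    auc_val, roc = classify.roc_auc(scores, y[test_idx], positive_label=1)
    report = classify.MetricsReport(
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=auc_val, roc=roc, confusion=cm,
    )
    table = pd.DataFrame(X, columns=columns)
    table.insert(0, "epoch_id", np.arange(len(epochs)))
    table["label"] = [e.label for e in epochs]
    table["split"] = "train"
    table.loc[test_idx, "split"] = "test"
    return table, report


def run_method_one(
    epochs: Sequence[EegEpoch], config: RunConfig | None = None
) -> tuple[pd.DataFrame, classify.MetricsReport]:
    """Signal-Range + Hurst classification of labeled epochs."""
    config = config or RunConfig(method="one")
    featurizer = MethodOneFeaturizer(k=config.topk, afa_order=config.afa_order)
    return _run(epochs, config, featurizer, ["signal_range", "mean_h"])


def run_method_two(
    epochs: Sequence[EegEpoch], config: RunConfig | None = None
) -> tuple[pd.DataFrame, classify.MetricsReport]:
    """Network-SVD classification of labeled epochs."""
    config = config or RunConfig(method="two")
    featurizer = MethodTwoFeaturizer(
        relative_alpha=config.relative_alpha, afa_order=config.afa_order
    )
    return _run(epochs, config, featurizer, ["s1sq_range", "s1sq_alpha", "s1sq_hurst"])


def run_localization(
    groups: dict[str, Sequence[Sequence[EegEpoch]]],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Cohort localization per discharge type.

    ``groups`` maps a discharge type to its subjects; each subject is a
    sequence of epochs whose per-epoch channel selections are merged by
    union before the cohort vote.  Returns a table with one row per type:
    (type, channels, per-channel frequency).
    """
    config = config or RunConfig()
    if not groups:
        raise ValueError("at least one discharge-type group is required")
    rows = []
    for kind, subjects in groups.items():
        if kind not in TEMPLATE_KINDS:
            raise ValueError(f"unknown discharge type: {kind!r}")
        if len(subjects) == 0:
            raise ValueError(f"empty subject group for type {kind!r}")
        subject_sets = []
        for epochs in subjects:
            per_epoch = [
                subject_localization(
                    all_difference_networks(
                        ep,
                        relative_alpha=config.relative_alpha,
                        afa_order=config.afa_order,
                    ),
                    config.localization,
                )
                for ep in epochs
            ]
            subject_sets.append(set().union(*per_epoch))
        selected = cohort_localization(subject_sets, config.localization)
        freqs = {
            ch: sum(ch in s for s in subject_sets) / len(subject_sets)
            for ch in CHANNELS
        }
        rows.append(
            {
                "type": kind,
                "channels": ";".join(ch for ch in CHANNELS if ch in selected),
                **{f"freq_{ch}": freqs[ch] for ch in CHANNELS},
            }
        )
    return pd.DataFrame(rows)


def phase_diagram(epoch: EegEpoch, lag: int = 1) -> np.ndarray:
    """Delay-embedding point set (s(t), s(t+lag)) of the channel-sum series.

    The spread of either coordinate equals the Signal Range of the summed
    signal, which makes these diagrams a quick visual range estimator.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    s = epoch.signals.sum(axis=0)
    if lag >= s.shape[0]:
        raise ValueError(f"lag {lag} >= series length {s.shape[0]}")
    return np.column_stack([s[:-lag], s[lag:]])
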