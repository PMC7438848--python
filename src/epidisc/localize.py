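"""Scalp localization of discharge types from network singular vectors.

For each feature network of a subject, every channel's column is projected
onto the first singular vector; the channel is retained when the absolute
cosine of that projection is at least 0.5.  "Projection coefficient" is
interpreted as the normalized (cosine) projection — an unnormalized dot
product would make the threshold unit-dependent — with the raw dot product
available as a mode.  The subject-level localization is the set of channels
common to all three networks (a 2-of-3 majority mode is provided), and the
cohort-level localization keeps channels selected in at least 55% of
subjects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .netsvd import FeatureNetwork, first_singular

__all__ = [
    "LocalizationConfig",
    "select_channels",
    "subject_localization",
    "cohort_localization",
]


@dataclass
class LocalizationConfig:
    """Thresholds for channel retention (both in (0, 1])."""

    projection_threshold: float = 0.5
    cohort_probability: float = 0.55
    projection_mode: str = "cosine"  # or "dot"
    combine: str = "intersection"  # or "majority" (>= 2 of 3 networks)

    def __post_init__(self) -> None:
        if not 0 < self.projection_threshold <= 1:
            raise ValueError("projection_threshold must lie in (0, 1]")
        if not 0 < self.cohort_probability <= 1:
            raise ValueError("cohort_probability must lie in (0, 1]")
        if self.projection_mode not in ("cosine", "dot"):
            raise ValueError(f"unknown projection mode {self.projection_mode!r}")
        if self.combine not in ("intersection", "majority"):
            raise ValueError(f"unknown combine mode {self.combine!r}")


def select_channels(
    network: FeatureNetwork | np.ndarray,
    u1: np.ndarray,
    threshold: float = 0.5,
    channel_names: Sequence[str] | None = None,
    mode: str = "cosine",
) -> set[str]:
    """Channels whose network column aligns with the first singular vector.

    Channel j is retained iff |<col_j / ||col_j||, u1>| >= threshold
    (cosine mode); zero columns are never retained.
    """
    if isinstance(network, FeatureNetwork):
        mat = network.matrix
        names = list(network.channel_names)
    else:
        mat = np.asarray(network, dtype=float)
        if channel_names is None:
            names = [str(i) for i in range(mat.shape[1])]
        else:
            names = list(channel_names)
    u1 = np.asarray(u1, dtype=float)
    if mat.shape[0] != u1.shape[0] or mat.shape[1] != len(names):
        raise ValueError("network / singular-vector / names dimension mismatch")
    norms = np.linalg.norm(mat, axis=0)
    proj = np.abs(u1 @ mat)
    if mode == "cosine":
        with np.errstate(invalid="ignore", divide="ignore"):
            proj = np.where(norms > 0, proj / np.maximum(norms, 1e-300), 0.0)
    elif mode != "dot":
        raise ValueError(f"unknown projection mode {mode!r}")
    keep = (proj >= threshold) & (norms > 0)
    return {names[j] for j in np.flatnonzero(keep)}


def subject_localization(
    networks: Mapping[str, FeatureNetwork] | Iterable[FeatureNetwork],
    config: LocalizationConfig | None = None,
) -> set[str]:
    """Channels common to the per-network selections of one subject/epoch."""
    config = config or LocalizationConfig()
    nets = list(networks.values()) if isinstance(networks, Mapping) else list(networks)
    if not nets:
        raise ValueError("at least one network is required")
    selections = []
    for net in nets:
        _, u1 = first_singular(net)
        selections.append(
            select_channels(
                net, u1,
                threshold=config.projection_threshold,
                mode=config.projection_mode,
            )
        )
    if config.combine == "intersection":
        out = set.intersection(*selections)
    else:
        counts = Counter(ch for sel in selections for ch in sel)
        out = {ch for ch, c in counts.items() if c >= 2}
    return out


def cohort_localization(
    subject_sets: Sequence[set[str]],
    config: LocalizationConfig | None = None,
) -> set[str]:
    """Channels selected in at least ``cohort_probability`` of subjects."""
    config = config or LocalizationConfig()
    if len(subject_sets) == 0:
        raise ValueError("cohort is empty")
    counts = Counter(ch for s in subject_sets for ch in s)
    n = len(subject_sets)
    return {ch for ch, c in counts.items() if c / n >= config.cohort_probability}
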