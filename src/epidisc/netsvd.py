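"""Channel-difference feature networks and their SVD features.

For one 19-channel epoch, the entry (i, j) of a feature network is a scalar
feature — Signal Range, relative alpha-band energy, or short-scale Hurst
exponent — of the difference series x_i - x_j.  All three features are
invariant under sign flip, so the networks are symmetric with zero diagonal
(the self-difference is the zero series; its Signal Range and alpha energy
are 0, and its Hurst exponent is set to 0 by convention).

The per-epoch classifier inputs are the squares of the largest singular
value of each network.  For a symmetric matrix the largest singular value
equals the largest absolute eigenvalue; the associated unit singular vector
(sign-fixed so its largest-magnitude entry is positive) drives the
localization procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import afa
from .channels import CHANNELS
from .features import band_energy, psd, epochs_to_array
from .io import EegEpoch

__all__ = [
    "FeatureNetwork",
    "SvdFeatures",
    "difference_network",
    "all_difference_networks",
    "first_singular",
    "method_two_features",
    "export_heatmap",
    "MethodTwoFeaturizer",
]

NETWORK_FEATURES = ("signal_range", "alpha_energy", "hurst")


@dataclass
class FeatureNetwork:
    """Symmetric feature matrix over channel differences."""

    matrix: np.ndarray
    feature: str
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channel_names)
        if self.matrix.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {self.matrix.shape}")


@dataclass
class SvdFeatures:
    """Squared first singular values of the three networks, in fixed order."""

    sigma1_sq_range: float
    sigma1_sq_alpha: float
    sigma1_sq_hurst: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sigma1_sq_range, self.sigma1_sq_alpha, self.sigma1_sq_hurst]
        )


def _pair_differences(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_ch = signals.shape[0]
    iu, ju = np.triu_indices(n_ch, k=1)
    return signals[iu] - signals[ju], iu, ju


def _fill_symmetric(values: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_ch: int) -> np.ndarray:
    mat = np.zeros((n_ch, n_ch))
    mat[iu, ju] = values
    mat[ju, iu] = values
    return mat


def _edge_features(
    signals: np.ndarray,
    fs: float,
    feature: str,
    relative_alpha: bool = True,
    afa_order: int = 2,
) -> np.ndarray:
    diffs, iu, ju = _pair_differences(signals)
    if feature == "signal_range":
        vals = diffs.max(axis=1) - diffs.min(axis=1)
    elif feature == "alpha_energy":
        vals = np.asarray(band_energy(psd(diffs, fs), "alpha", relative=relative_alpha))
    elif feature == "hurst":
        vals, _, _ = afa.hurst_batch(diffs, order=afa_order)
    else:
        raise ValueError(f"unknown network feature: {feature!r}")
    return _fill_symmetric(vals, iu, ju, signals.shape[0])


def difference_network(
    epoch: EegEpoch,
    feature: str,
    relative_alpha: bool = True,
    afa_order: int = 2,
) -> FeatureNetwork:
    """Build one 19x19 channel-difference network for the given feature."""
    if epoch.signals.shape[0] != len(epoch.channel_names):
        raise ValueError("channel count mismatch")
    mat = _edge_features(
        epoch.signals, epoch.fs, feature,
        relative_alpha=relative_alpha, afa_order=afa_order,
    )
    return FeatureNetwork(matrix=mat, feature=feature, channel_names=epoch.channel_names)


def all_difference_networks(
    epoch: EegEpoch, relative_alpha: bool = True, afa_order: int = 2
) -> dict[str, FeatureNetwork]:
    """The three networks of one epoch, sharing one pass over the pair series."""
    diffs, iu, ju = _pair_differences(epoch.signals)
    n_ch = epoch.signals.shape[0]
    rng_vals = diffs.max(axis=1) - diffs.min(axis=1)
    alpha_vals = np.asarray(
        band_energy(psd(diffs, epoch.fs), "alpha", relative=relative_alpha)
    )
    h_vals, _, _ = afa.hurst_batch(diffs, order=afa_order)
    return {
        "signal_range": FeatureNetwork(
            _fill_symmetric(rng_vals, iu, ju, n_ch), "signal_range", epoch.channel_names
        ),
        "alpha_energy": FeatureNetwork(
            _fill_symmetric(alpha_vals, iu, ju, n_ch), "alpha_energy", epoch.channel_names
        ),
        "hurst": FeatureNetwork(
            _fill_symmetric(h_vals, iu, ju, n_ch), "hurst", epoch.channel_names
        ),
    }


def first_singular(network: FeatureNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Largest singular value and its unit left singular vector.

    The vector's sign is fixed so its largest-magnitude entry is positive,
    making downstream localization deterministic.
    """
    mat = network.matrix if isinstance(network, FeatureNetwork) else np.asarray(network, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.all(np.isfinite(mat)):
        raise ValueError("matrix contains non-finite entries")
    u, s, _ = np.linalg.svd(mat)
    u1 = u[:, 0]
    pivot = np.argmax(np.abs(u1))
    if u1[pivot] < 0:
        u1 = -u1
    return float(s[0]), u1


def method_two_features(
    epoch: EegEpoch, relative_alpha: bool = True, afa_order: int = 2
) -> SvdFeatures:
    """sigma_1^2 of the range, alpha and Hurst networks of one epoch."""
    nets = all_difference_networks(epoch, relative_alpha=relative_alpha, afa_order=afa_order)
    vals = {}
    for name in NETWORK_FEATURES:
        s1, _ = first_singular(nets[name])
        vals[name] = s1**2
    return SvdFeatures(
        sigma1_sq_range=vals["signal_range"],
        sigma1_sq_alpha=vals["alpha_energy"],
        sigma1_sq_hurst=vals["hurst"],
    )


def export_heatmap(
    network: FeatureNetwork, path: str | Path, image: bool = True
) -> None:
    """Write the network as CSV (and a PNG heat map alongside).

    ``path`` names the CSV file; the image replaces its suffix with .png.
    """
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(
        network.matrix, index=network.channel_names, columns=network.channel_names
    )
    df.to_csv(path)
    if image:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(network.matrix, cmap="viridis")
        ticks = np.arange(len(network.channel_names))
        ax.set_xticks(ticks, network.channel_names, rotation=90, fontsize=6)
        ax.set_yticks(ticks, network.channel_names, fontsize=6)
        ax.set_title(f"{network.feature} network")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=150)
        plt.close(fig)


class MethodTwoFeaturizer(BaseEstimator, TransformerMixin):
    """Transform epochs into the three sigma_1^2 network features."""

    def __init__(self, relative_alpha: bool = True, afa_order: int = 2, fs: float = 256.0):
        self.relative_alpha = relative_alpha
        self.afa_order = afa_order
        self.fs = fs

    def fit(self, X, y=None):
        arr = epochs_to_array(X)
        self.n_channels_ = arr.shape[1]
        self.n_samples_ = arr.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        epochs = X if not isinstance(X, np.ndarray) else None
        arr = epochs_to_array(X)
        out = np.empty((arr.shape[0], 3))
        for i in range(arr.shape[0]):
            fs = epochs[i].fs if epochs is not None else self.fs
            names = (
                epochs[i].channel_names
                if epochs is not None
                else tuple(f"ch{j}" for j in range(arr.shape[1]))
            )
            ep = EegEpoch(signals=arr[i], fs=fs, channel_names=names)
            out[i] = method_two_features(
                ep, relative_alpha=self.relative_alpha, afa_order=self.afa_order
            ).as_array()
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(["s1sq_range", "s1sq_alpha", "s1sq_hurst"])
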