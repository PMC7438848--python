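"""Per-series scalar features and the Signal-Range/Hurst feature pair.

Signal Range of a series over an epoch is simply max - min; the per-epoch
statistic is the mean of the 10 largest per-channel ranges.  Band energies
come from a Welch power spectral density (1 s Hann segments, 50% overlap)
integrated over the clinical bands; "relative" alpha energy divides by the
total 0.5-70 Hz power.

``MethodOneFeaturizer`` packages the (top-10 mean Signal Range, mean
short-scale Hurst exponent) pair as a scikit-learn transformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from sklearn.base import BaseEstimator, TransformerMixin

from . import afa
from .io import EegEpoch

__all__ = [
    "BANDS",
    "MethodOneFeatures",
    "signal_range",
    "topk_mean_range",
    "psd",
    "band_energy",
    "method_one_features",
    "MethodOneFeaturizer",
    "epochs_to_array",
]

#: Clinical EEG frequency bands in Hz (gamma capped at the 70 Hz bandwidth).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 70.0),
}

TOTAL_BAND = (0.5, 70.0)


@dataclass
class MethodOneFeatures:
    """Per-epoch classifier inputs for the Signal-Range + Hurst method."""

    signal_range: float
    mean_h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.signal_range, self.mean_h])


def signal_range(x: np.ndarray) -> float:
    """Max minus min of the series over the whole epoch (µV)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("signal_range of an empty series is undefined")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN or Inf")
    return float(x.max() - x.min())


def topk_mean_range(epoch: EegEpoch | np.ndarray, k: int = 10) -> float:
    """Mean of the k largest per-channel Signal Ranges."""
    x = epoch.signals if isinstance(epoch, EegEpoch) else np.asarray(epoch, dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} available channels")
    ranges = x.max(axis=1) - x.min(axis=1)
    top = np.sort(ranges)[-k:]
    return float(top.mean())


def psd(x: np.ndarray, fs: float, nperseg: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (µV²/Hz).

    Uses 1 s Hann-tapered segments with 50% overlap by default, which
    stabilizes the estimate on a 4 s epoch.  Satisfies Parseval: the
    integral of the density approximates the variance of the detrended
    series.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 256:
        raise ValueError(f"series length {x.shape[-1]} < 256")
    if nperseg is None:
        nperseg = int(round(fs))
    nperseg = min(int(nperseg), x.shape[-1])
    freqs, density = _sig.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", axis=-1,
    )
    return freqs, density


def band_energy(
    spectrum: tuple[np.ndarray, np.ndarray],
    band: str | tuple[float, float] = "alpha",
    relative: bool = True,
) -> np.ndarray | float:
    """Trapezoidal integral of the PSD over a band, optionally relative.

    ``relative`` divides by the integral over the full 0.5-70 Hz analysis
    bandwidth, giving a value in [0, 1].  Works on a batch of spectra
    (density rows) as well as a single one.
    """
    freqs, density = spectrum
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if not (0 <= lo < hi <= freqs.max() + 1e-9):
        raise ValueError(f"invalid band ({lo}, {hi}) for spectrum up to {freqs.max()} Hz")

    def integrate(f_lo: float, f_hi: float) -> np.ndarray:
        mask = (freqs >= f_lo) & (freqs <= f_hi)
        return np.trapezoid(density[..., mask], freqs[mask], axis=-1)

    energy = integrate(lo, hi)
    if relative:
        total = integrate(*TOTAL_BAND)
        with np.errstate(invalid="ignore", divide="ignore"):
            energy = np.where(total > 0, energy / np.maximum(total, 1e-300), 0.0)
    if np.ndim(energy) == 0:
        return float(energy)
    return energy


def method_one_features(
    epoch: EegEpoch,
    k: int = 10,
    afa_order: int = 2,
    w_grid: np.ndarray | None = None,
) -> MethodOneFeatures:
    """(top-10 mean Signal Range, mean per-channel short-scale H)."""
    h_short, _, _ = afa.hurst_batch(epoch.signals, w_grid=w_grid, order=afa_order)
    return MethodOneFeatures(
        signal_range=topk_mean_range(epoch, k=k),
        mean_h=float(h_short.mean()),
    )


def epochs_to_array(X) -> np.ndarray:
    """Coerce a list of epochs or a 3-D array to (n_epochs, n_ch, n_samp)."""
    if isinstance(X, np.ndarray):
        if X.ndim != 3:
            raise ValueError("expected a 3-D (epochs, channels, samples) array")
        return X.astype(float, copy=False)
    return np.stack([np.asarray(e.signals, dtype=float) for e in X])


class MethodOneFeaturizer(BaseEstimator, TransformerMixin):
    """Transform epochs into the 2-D (signal_range, mean_h) feature space.

    Accepts either a list of :class:`~epidisc.io.EegEpoch` or a 3-D array of
    shape (n_epochs, n_channels, n_samples).  Stateless apart from input
    validation, so it composes with sklearn pipelines and model selection.
    """

    def __init__(self, k: int = 10, afa_order: int = 2):
        self.k = k
        self.afa_order = afa_order

    def fit(self, X, y=None):
        arr = epochs_to_array(X)
        self.n_channels_ = arr.shape[1]
        self.n_samples_ = arr.shape[2]
        if self.k > self.n_channels_:
            raise ValueError(f"k={self.k} exceeds {self.n_channels_} channels")
        return self

    def transform(self, X) -> np.ndarray:
        arr = epochs_to_array(X)
        out = np.empty((arr.shape[0], 2))
        for i, sig in enumerate(arr):
            f = method_one_features(
                EegEpoch(signals=sig, fs=256.0, channel_names=tuple(f"ch{j}" for j in range(sig.shape[0]))),
                k=self.k,
                afa_order=self.afa_order,
            )
            out[i] = f.as_array()
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(["signal_range", "mean_h"])
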