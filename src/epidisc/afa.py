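"""Adaptive fractal analysis (AFA) for Hurst-exponent estimation.

AFA estimates the Hurst exponent H of a (possibly nonstationary, noisy)
series x by:

1. integrating the mean-removed series into a random-walk profile
   u(n) = sum_{k<=n} (x(k) - xbar);
2. for each odd window size w, fitting order-M polynomials in windows that
   overlap by (w+1)/2 samples and crossfading the overlapped fits into one
   smooth global trend v;
3. computing the residual fluctuation F(w) = sqrt(mean((u - v)^2)), which
   scales as F(w) ~ w^H for fractal processes;
4. regressing log2 F on log2 w.  Scalp EEG typically shows two scaling
   regimes; a two-segment piecewise-linear fit yields the short-scale
   exponent ``h_short`` (the discriminative quantity here) and the
   long-scale exponent ``h_long``.

The crossfade over an overlap of n = (w+1)/2 samples weights the earlier
fit by 1 - (l-1)/(n-1) and the later fit by (l-1)/(n-1) at overlap position
l = 1..n; the first and last half-windows take their single covering fit
unweighted.  This makes the trend reproduce any polynomial of degree <= M
exactly.

All heavy routines accept a batch of series at once (rows of a 2-D array);
per-epoch network construction runs hundreds of AFA estimates, and batching
keeps that vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "RandomWalkProfile",
    "ScalingCurve",
    "random_walk",
    "global_trend",
    "fluctuation",
    "scaling_curve",
    "fit_two_regimes",
    "hurst",
    "hurst_batch",
    "default_window_grid",
]

MIN_SERIES_LEN = 64  # slope fits on fewer scales are unstable


@dataclass
class RandomWalkProfile:
    """Integrated mean-removed series (the 'random walk' AFA operates on)."""

    u: np.ndarray
    mean_removed: float

    @property
    def n(self) -> int:
        return self.u.shape[-1]


@dataclass
class ScalingCurve:
    """log2 F(w) versus log2 w, with two-regime slopes once fitted."""

    w_grid: np.ndarray
    logF: np.ndarray
    fit_order: int
    h_short: float | None = None
    h_long: float | None = None
    breakpoint: int | None = None

    @property
    def log_w(self) -> np.ndarray:
        return np.log2(self.w_grid.astype(float))


def _validate_series(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("series must have length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN or Inf")
    return x


def random_walk(x: np.ndarray) -> RandomWalkProfile:
    """Integrate the mean-removed series; the profile ends at 0 exactly."""
    x = _validate_series(x)
    if x.ndim != 1:
        raise ValueError("random_walk expects a 1-D series")
    xbar = float(x.mean())
    return RandomWalkProfile(u=np.cumsum(x - xbar), mean_removed=xbar)


def _window_starts(n: int, w: int) -> np.ndarray:
    step = (w - 1) // 2
    starts = list(range(0, n - w + 1, step))
    if starts[-1] != n - w:
        starts.append(n - w)
    return np.asarray(starts)


def _check_window(w: int, n: int, order: int) -> None:
    if w % 2 == 0:
        raise ValueError(f"window size must be odd, got {w}")
    if not 3 <= w <= n:
        raise ValueError(f"window size {w} out of range [3, {n}]")
    if order not in (1, 2):
        raise ValueError(f"polynomial order must be 1 or 2, got {order}")


@lru_cache(maxsize=256)
def _detrend_plan(N: int, w: int, order: int):
    """Cached geometry shared by every series of the same length: window
    starts, local Vandermonde basis with its pseudo-inverse, crossfade
    weights, and the weight-sum denominator."""
    starts = _window_starts(N, w)
    # centered, scaled local coordinate keeps the Vandermonde well conditioned
    t = (np.arange(w) - (w - 1) / 2.0) / w
    V = np.vander(t, order + 1, increasing=True)  # (w, order+1)
    pinv = np.linalg.pinv(V)  # (order+1, w)

    n_half = (w + 1) // 2
    ramp = np.minimum(np.arange(w), w - 1 - np.arange(w)) / max(n_half - 1, 1)
    ramp = np.minimum(ramp, 1.0)
    weights = np.tile(ramp, (len(starts), 1))
    weights[0, : n_half - 1] = 1.0  # first half-window: single covering fit
    weights[-1, w - n_half + 1 :] = 1.0  # last half-window likewise

    den = np.zeros(N)
    for k, s in enumerate(starts):
        den[s : s + w] += weights[k]

    idx = starts[:, None] + np.arange(w)[None, :]  # (K, w)
    return starts, idx, V, pinv, weights, den


def _detrend_batch(U: np.ndarray, w: int, order: int) -> np.ndarray:
    """Global adaptive trend for each row of ``U`` (B, N) at window size w."""
    B, N = U.shape
    starts, idx, V, pinv, weights, den = _detrend_plan(N, w, order)

    Uw = U[:, idx]  # (B, K, w)
    coef = Uw @ pinv.T  # (B, K, order+1)
    fits = coef @ V.T  # (B, K, w)
    fits *= weights[None, :, :]

    num = np.zeros((B, N))
    for k, s in enumerate(starts):
        num[:, s : s + w] += fits[:, k, :]
    return num / den


def global_trend(profile: RandomWalkProfile | np.ndarray, w: int, order: int = 2) -> np.ndarray:
    """Stitched overlapped-window polynomial trend of the profile."""
    u = profile.u if isinstance(profile, RandomWalkProfile) else np.asarray(profile, dtype=float)
    _check_window(w, u.shape[-1], order)
    return _detrend_batch(u[None, :], w, order)[0]


def fluctuation(profile: RandomWalkProfile | np.ndarray, w: int, order: int = 2) -> float:
    """Root-mean-square residual of the profile around its global trend."""
    u = profile.u if isinstance(profile, RandomWalkProfile) else np.asarray(profile, dtype=float)
    v = global_trend(u, w, order)
    return float(np.sqrt(np.mean((u - v) ** 2)))


DEFAULT_MIN_WINDOW = 17


def default_window_grid(n: int, min_w: int = DEFAULT_MIN_WINDOW) -> np.ndarray:
    """Dyadic-plus-intermediate odd window sizes in [min_w, n/2].

    Windows below ~17 samples leave an order-2 fit too few residual degrees
    of freedom: the detrending absorbs a scale-dependent share of the
    fluctuation and visibly bends the small-w end of the log-log curve, so
    the default grid starts at 17 (66 ms at 256 Hz).  Pass ``min_w=5`` to
    inspect the full curve.
    """
    ws = {2**k + 1 for k in range(2, max(int(np.log2(n / 4)), 2) + 1)}
    ws |= {7, 11, 25, 49, 97, 193, 385}
    grid = sorted(w for w in ws if max(min_w, 5) <= w <= n // 2)
    if not grid:
        raise ValueError(f"series of length {n} leaves no valid window sizes")
    return np.asarray(grid)


def _scaling_curves_batch(
    X: np.ndarray, w_grid: np.ndarray, order: int
) -> np.ndarray:
    """log2 F(w) for each row of X (B, N) -> (B, G)."""
    U = np.cumsum(X - X.mean(axis=1, keepdims=True), axis=1)
    logF = np.empty((X.shape[0], len(w_grid)))
    for j, w in enumerate(w_grid):
        V = _detrend_batch(U, int(w), order)
        F = np.sqrt(np.mean((U - V) ** 2, axis=1))
        with np.errstate(divide="ignore"):
            logF[:, j] = np.log2(F)
    return logF


def scaling_curve(
    x: np.ndarray, w_grid: np.ndarray | None = None, order: int = 2
) -> ScalingCurve:
    """Compute log2 F(w) over the window grid (slopes left unfitted)."""
    x = _validate_series(x)
    if x.ndim != 1:
        raise ValueError("scaling_curve expects a 1-D series")
    n = x.shape[0]
    if n < MIN_SERIES_LEN:
        raise ValueError(f"series length {n} < {MIN_SERIES_LEN}")
    if w_grid is None:
        w_grid = default_window_grid(n)
    w_grid = np.asarray(w_grid, dtype=int)
    if w_grid.size == 0:
        raise ValueError("window grid is empty")
    for w in w_grid:
        _check_window(int(w), n, order)
        if w > n // 2:
            raise ValueError(f"window size {w} exceeds N/2 = {n // 2}")
    logF = _scaling_curves_batch(x[None, :], w_grid, order)[0]
    return ScalingCurve(w_grid=w_grid, logF=logF, fit_order=order)


def _two_regime_batch(
    logw: np.ndarray, logF: np.ndarray, min_seg: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best two-segment linear fit per row of logF.

    Returns (h_short, h_long, breakpoint) arrays; the breakpoint is the index
    of the first grid point of the long-scale segment.
    """
    G = logw.shape[0]
    B = logF.shape[0]
    if G < 2 * min_seg:
        raise ValueError(f"need at least {2 * min_seg} grid points, got {G}")

    def seg_fit(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        A = np.column_stack([logw[lo:hi], np.ones(hi - lo)])
        pinv = np.linalg.pinv(A)
        coef = logF[:, lo:hi] @ pinv.T  # (B, 2)
        resid = logF[:, lo:hi] - coef @ A.T
        return coef[:, 0], np.sum(resid**2, axis=1)

    best_sse = np.full(B, np.inf)
    best_bp = np.zeros(B, dtype=int)
    best_hs = np.zeros(B)
    best_hl = np.zeros(B)
    for bp in range(min_seg, G - min_seg + 1):
        hs, sse1 = seg_fit(0, bp)
        hl, sse2 = seg_fit(bp, G)
        sse = sse1 + sse2
        better = sse < best_sse - 1e-12
        best_sse = np.where(better, sse, best_sse)
        best_bp = np.where(better, bp, best_bp)
        best_hs = np.where(better, hs, best_hs)
        best_hl = np.where(better, hl, best_hl)
    return best_hs, best_hl, best_bp


def fit_two_regimes(curve: ScalingCurve, min_seg: int = 3) -> tuple[float, float, int]:
    """Fit two straight lines to the scaling curve, splitting where the total
    squared error is minimal with at least ``min_seg`` points per segment.

    Sets and returns ``(h_short, h_long, breakpoint)``.
    """
    if not np.all(np.isfinite(curve.logF)):
        raise ValueError("scaling curve contains non-finite log-fluctuations")
    hs, hl, bp = _two_regime_batch(curve.log_w, curve.logF[None, :], min_seg)
    curve.h_short = float(hs[0])
    curve.h_long = float(hl[0])
    curve.breakpoint = int(bp[0])
    return curve.h_short, curve.h_long, curve.breakpoint


def hurst(
    x: np.ndarray, w_grid: np.ndarray | None = None, order: int = 2
) -> ScalingCurve:
    """Full AFA estimate: scaling curve with fitted two-regime slopes."""
    curve = scaling_curve(x, w_grid=w_grid, order=order)
    fit_two_regimes(curve)
    return curve


def hurst_batch(
    X: np.ndarray,
    w_grid: np.ndarray | None = None,
    order: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short- and long-scale Hurst exponents for each row of ``X``.

    Rows that are exactly constant (zero fluctuation at every scale) get
    H = 0 by convention; they arise only as the self-difference of a channel.
    Returns (h_short, h_long, breakpoint) arrays of length B.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("hurst_batch expects a 2-D (series, samples) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains NaN or Inf")
    n = X.shape[1]
    if n < MIN_SERIES_LEN:
        raise ValueError(f"series length {n} < {MIN_SERIES_LEN}")
    if w_grid is None:
        w_grid = default_window_grid(n)
    w_grid = np.asarray(w_grid, dtype=int)
    logF = _scaling_curves_batch(X, w_grid, order)
    degenerate = ~np.all(np.isfinite(logF), axis=1)
    h_short = np.zeros(X.shape[0])
    h_long = np.zeros(X.shape[0])
    bp = np.zeros(X.shape[0], dtype=int)
    if np.any(~degenerate):
        hs, hl, b = _two_regime_batch(np.log2(w_grid.astype(float)), logF[~degenerate])
        h_short[~degenerate] = hs
        h_long[~degenerate] = hl
        bp[~degenerate] = b
    return h_short, h_long, bp
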