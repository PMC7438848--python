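"""Adaptive fractal analysis: profile, trend stitching, scaling, regimes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epidisc import gen_fgn, hurst
from epidisc.afa import (
    ScalingCurve,
    _window_starts,
    default_window_grid,
    fit_two_regimes,
    fluctuation,
    global_trend,
    random_walk,
    scaling_curve,
)


def test_random_walk_examples():
    np.testing.assert_allclose(random_walk([1.0, 2.0, 3.0]).u, [-1.0, -1.0, 0.0])
    np.testing.assert_allclose(random_walk(np.full(10, 3.3)).u, np.zeros(10), atol=1e-12)


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
def test_random_walk_telescopes_to_zero(xs):
    u = random_walk(np.asarray(xs)).u
    assert abs(u[-1]) <= 1e-6 * max(1.0, np.max(np.abs(xs)))


def test_random_walk_rejects_nonfinite():
    with pytest.raises(ValueError):
        random_walk([1.0, np.nan, 2.0])


@pytest.mark.parametrize("w", [5, 11, 21])
def test_trend_reproduces_line(w):
    i = np.arange(64, dtype=float)
    u = 2 * i + 3
    v = global_trend(u, w, order=1)
    np.testing.assert_allclose(v, u, atol=1e-8)


def test_trend_reproduces_quadratic():
    i = np.arange(100, dtype=float)
    u = i**2
    v = global_trend(u, 15, order=2)
    np.testing.assert_allclose(v, u, atol=1e-6)


def _oracle_trend(u, w, order):
    """Naive re-implementation of the stitching rule: per-window polyfit,
    triangular crossfade over overlaps, unweighted first/last half-window,
    accumulated point by point."""
    n = len(u)
    starts = list(_window_starts(n, w))
    n_half = (w + 1) // 2
    num = np.zeros(n)
    den = np.zeros(n)
    for k, s in enumerate(starts):
        idx = np.arange(s, s + w)
        coeffs = np.polyfit(idx, u[idx], order)
        fit = np.polyval(coeffs, idx)
        for local, j in enumerate(idx):
            wt = min(local, w - 1 - local) / (n_half - 1)
            wt = min(wt, 1.0)
            if k == 0 and local < n_half - 1:
                wt = 1.0
            if k == len(starts) - 1 and local > w - n_half:
                wt = 1.0
            num[j] += wt * fit[local]
            den[j] += wt
    return num / den


def test_trend_matches_independent_implementation(rng):
    u = np.cumsum(rng.normal(size=64))
    v = global_trend(u, 11, order=1)
    np.testing.assert_allclose(v, _oracle_trend(u, 11, 1), atol=1e-10)
    v2 = global_trend(u, 13, order=2)
    np.testing.assert_allclose(v2, _oracle_trend(u, 13, 2), atol=1e-10)


def test_trend_translation_equivariance(rng):
    u = np.cumsum(rng.normal(size=128))
    np.testing.assert_allclose(
        global_trend(u + 17.0, 21, 2), global_trend(u, 21, 2) + 17.0, atol=1e-8
    )


def test_trend_rejects_even_or_oversized_window():
    u = np.arange(32, dtype=float)
    with pytest.raises(ValueError):
        global_trend(u, 10, 1)
    with pytest.raises(ValueError):
        global_trend(u, 33, 1)


def test_fluctuation_properties(rng):
    i = np.arange(64, dtype=float)
    assert fluctuation(3 * i + 1, 11, order=1) < 1e-8
    u = np.cumsum(rng.normal(size=128))
    f = fluctuation(u, 17, 2)
    assert fluctuation(2 * u, 17, 2) == pytest.approx(2 * f, rel=1e-10)
    # brute-force RMS of the residual
    resid = u - global_trend(u, 17, 2)
    assert f == pytest.approx(float(np.sqrt(np.mean(resid**2))), abs=1e-12)


def test_scaling_curve_white_noise_slope():
    slopes = []
    for s in range(20):
        x = gen_fgn(0.5, 4096, seed=500 + s)
        c = scaling_curve(x)
        slopes.append(np.polyfit(c.log_w, c.logF, 1)[0])
    assert abs(np.mean(slopes) - 0.5) < 0.05


def test_scaling_curve_fgn_075_slope():
    slopes = []
    for s in range(20):
        x = gen_fgn(0.75, 4096, seed=900 + s)
        c = scaling_curve(x)
        slopes.append(np.polyfit(c.log_w, c.logF, 1)[0])
    assert abs(np.mean(slopes) - 0.75) < 0.05


def test_scaling_curve_rejects_short_series():
    with pytest.raises(ValueError):
        scaling_curve(np.random.default_rng(0).normal(size=32))


def test_fit_two_regimes_exact_piecewise():
    logw = np.arange(12, dtype=float)
    # two disjoint straight lines: slope 0.8 (first 6 points), 0.3 (last 6)
    logF = np.where(logw < 6, 0.8 * logw, 10.0 + 0.3 * logw)
    curve = ScalingCurve(w_grid=(2**logw).astype(int), logF=logF, fit_order=2)
    hs, hl, bp = fit_two_regimes(curve)
    assert hs == pytest.approx(0.8, abs=1e-9)
    assert hl == pytest.approx(0.3, abs=1e-9)
    assert bp == 6


def test_fit_two_regimes_globally_linear():
    logw = np.linspace(2, 8, 10)
    curve = ScalingCurve(w_grid=np.round(2**logw).astype(int), logF=0.6 * logw + 1, fit_order=2)
    # grid here is only a carrier; slopes are defined against log2 of it
    curve.logF = 0.6 * np.log2(curve.w_grid.astype(float)) + 1.0
    hs, hl, _ = fit_two_regimes(curve)
    assert abs(hs - hl) < 1e-6
    assert hs == pytest.approx(0.6, abs=1e-6)


def test_fit_two_regimes_noisy_recovery(rng):
    logw = np.arange(14, dtype=float)
    truth = np.where(logw < 7, 0.8 * logw, 0.8 * 6 + 0.3 * (logw - 6))
    errs = []
    for _ in range(50):
        noisy = truth + rng.normal(0, 0.01, size=truth.size)
        curve = ScalingCurve(w_grid=(2**logw).astype(int), logF=noisy, fit_order=2)
        hs, _, _ = fit_two_regimes(curve)
        errs.append(abs(hs - 0.8))
    assert np.mean(errs) < 0.05


def test_fit_two_regimes_needs_six_points():
    curve = ScalingCurve(w_grid=np.array([5, 9, 17, 33]), logF=np.arange(4.0), fit_order=2)
    with pytest.raises(ValueError):
        fit_two_regimes(curve)


def test_hurst_end_to_end_on_fgn():
    """Short-scale slope from the full pipeline tracks the true exponent."""
    errs = []
    for s in range(10):
        x = gen_fgn(0.7, 4096, seed=40 + s)
        c = hurst(x)
        errs.append(abs(c.h_short - 0.7))
    assert np.mean(errs) < 0.08


def test_default_grid_bounds():
    g = default_window_grid(1024)
    assert g[0] >= 5 and g[-1] <= 512
    assert np.all(g % 2 == 1)
    assert np.all(np.diff(g) > 0)
    full = default_window_grid(1024, min_w=5)
    assert full[0] == 5
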