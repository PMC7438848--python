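"""Synthetic EEG generator: fGn exactness, template shapes, planting."""

import numpy as np
import pytest

from epidisc import (
    CHANNELS,
    DEFAULT_TYPE_COUNTS,
    SynthConfig,
    TEMPLATE_KINDS,
    gen_dataset,
    gen_epoch,
    gen_fgn,
    make_template,
)
from epidisc.features import psd, topk_mean_range


def fgn_autocov(h, sd, lags):
    k = np.asarray(lags, dtype=float)
    return (sd**2 / 2) * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))


@pytest.mark.parametrize("h", [0.3, 0.5, 0.8])
def test_fgn_autocovariance_matches_closed_form(h):
    """Sample autocovariance at lags 0..5 matches the fGn closed form."""
    sd = 2.0
    x = gen_fgn(h, 2048, sd=sd, seed=11, size=200)
    emp = []
    for lag in range(6):
        if lag == 0:
            emp.append(np.mean(x * x))
        else:
            emp.append(np.mean(x[:, :-lag] * x[:, lag:]))
    expected = fgn_autocov(h, sd, range(6))
    assert np.allclose(emp, expected, atol=0.05 * sd**2)


def test_fgn_h_half_is_white_noise():
    x = gen_fgn(0.5, 4096, seed=3)
    r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert abs(r1) < 3 / np.sqrt(4096)


def test_fgn_deterministic_and_validated():
    a = gen_fgn(0.7, 256, sd=1.5, seed=9)
    b = gen_fgn(0.7, 256, sd=1.5, seed=9)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        gen_fgn(1.2, 100)
    with pytest.raises(ValueError):
        gen_fgn(0.5, 1)


def test_spike_template_arithmetic():
    t = make_template("spike", fs=256.0, duration_ms=40.0, amplitude=100.0)
    assert t.waveform.shape[0] == round(40 * 256 / 1000)
    rng_ = t.waveform.max() - t.waveform.min()
    assert abs(rng_ - 100.0) <= 5.0


@pytest.mark.parametrize("kind", TEMPLATE_KINDS)
def test_template_invariants(kind):
    """Every generated template respects its clinical duration/amplitude box."""
    t = make_template(kind, fs=256.0)
    assert t.waveform.ndim == 1 and t.waveform.size > 0
    peak_to_trough = t.waveform.max() - t.waveform.min()
    if kind == "spike":
        assert 20 <= t.duration_ms <= 70
        assert peak_to_trough > 50
    elif kind == "sharp":
        assert 70 <= t.duration_ms <= 200
        assert 100 * 0.95 <= peak_to_trough <= 200 * 1.05
    elif kind == "spike_rhythm":
        assert t.duration_ms >= 1000
        assert 100 * 0.95 <= peak_to_trough <= 200 * 1.05
    # composite kinds: total length = sum of parts, still sampled at fs
    assert t.waveform.shape[0] == pytest.approx(t.duration_ms * t.fs / 1000, abs=t.fs / 100)


def test_template_range_validation():
    with pytest.raises(ValueError):
        make_template("polyspike", n_spikes=1)
    with pytest.raises(ValueError):
        make_template("spike", duration_ms=10.0)
    with pytest.raises(ValueError):
        make_template("spike", amplitude=40.0)
    with pytest.raises(ValueError):
        make_template("spike_rhythm", rhythm_duration_s=0.5)
    with pytest.raises(ValueError):
        make_template("not_a_kind")


def test_spike_rhythm_psd_peak():
    t = make_template("spike_rhythm", fs=256.0, freq=15.0, rhythm_duration_s=1.5)
    freqs, dens = psd(t.waveform, 256.0)
    # ignore the DC/slow ramp from the one-sided bump train
    mask = freqs >= 5.0
    peak = freqs[mask][np.argmax(dens[mask])]
    assert abs(peak - 15.0) <= 1.0


def test_gen_epoch_normal_has_no_focal_set(normal_epoch):
    assert normal_epoch.focal_channels == ()
    assert normal_epoch.signals.shape == (19, 1024)
    assert normal_epoch.label == "normal"


def test_gen_epoch_deterministic():
    a = gen_epoch("spike", seed=5)
    b = gen_epoch("spike", seed=5)
    np.testing.assert_array_equal(a.signals, b.signals)
    assert a.focal_channels == b.focal_channels


def test_planted_spike_raises_focal_range():
    """A 150 µV spike on F7/T3 over 15 µV background lifts F7's range above
    a non-focal channel's in nearly every epoch."""
    cfg = SynthConfig(focal_channels=("F7", "T3"))
    i_f7, i_pz = CHANNELS.index("F7"), CHANNELS.index("Pz")
    wins = 0
    for s in range(100):
        ep = gen_epoch("spike", cfg, seed=7000 + s)
        r = ep.signals.max(axis=1) - ep.signals.min(axis=1)
        wins += r[i_f7] > r[i_pz]
    assert wins >= 95


def test_gen_dataset_default_catalog():
    assert sum(DEFAULT_TYPE_COUNTS.values()) == 540
    data = gen_dataset(n_normal=4, n_per_type=(1, 1, 1, 1, 1, 1, 1), seed=2)
    assert len(data) == 11
    labels = sorted(e.label for e in data)
    assert labels.count("normal") == 4
    for kind in TEMPLATE_KINDS:
        assert labels.count(kind) == 1


def test_gen_dataset_empty_and_deterministic():
    assert gen_dataset(n_normal=0, n_per_type=(0,) * 7, seed=1) == []
    a = gen_dataset(n_normal=3, n_per_type=(2, 0, 0, 0, 0, 0, 0), seed=4)
    b = gen_dataset(n_normal=3, n_per_type=(2, 0, 0, 0, 0, 0, 0), seed=4)
    assert [e.label for e in a] == [e.label for e in b]
    for ea, eb in zip(a, b):
        np.testing.assert_array_equal(ea.signals, eb.signals)


def test_synth_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(h_normal=1.5)
    with pytest.raises(ValueError):
        SynthConfig(focal_channels=("XX",))
    with pytest.raises(ValueError):
        SynthConfig(attenuation=0.0)
    with pytest.raises(ValueError):
        gen_epoch("no_such_label")


def test_occipital_alpha_doubling():
    """O1/O2 carry twice the alpha amplitude of other channels."""
    cfg = SynthConfig(bg_sd=0.5, alpha_amp_normal=10.0)
    ep = gen_epoch("normal", cfg, seed=31)
    from epidisc.features import band_energy

    freqs, dens = psd(ep.signals, 256.0)
    alpha = band_energy((freqs, dens), "alpha", relative=False)
    occ = [CHANNELS.index(c) for c in ("O1", "O2")]
    rest = [i for i in range(19) if i not in occ]
    assert np.min(alpha[occ]) > 2 * np.max(alpha[rest])
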