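"""Synthetic 19-channel EEG with known ground truth.

Each epoch is a sum of three ingredients whose parameters the downstream
stages are designed to detect:

* fractal background activity — fractional Gaussian noise (fGn) with a
  class-dependent Hurst exponent, generated exactly by circulant embedding;
* an alpha-band (8-13 Hz) rhythm with per-channel random phase, stronger in
  the discharge class and doubled occipitally (O1/O2);
* for discharge epochs, one of seven epileptiform transient templates
  (spike, sharp, spike/sharp-and-slow-wave complexes, polyspike variants,
  spike rhythm) planted on a focal channel subset and attenuated with scalp
  graph distance.

Template duration/amplitude conventions follow standard clinical EEG
definitions: spikes last 20-70 ms with amplitude above 50 µV; sharp waves
last 70-200 ms at 100-200 µV, usually negative-going; polyspike complexes
contain two or more spikes; a spike rhythm is a 10-25 Hz spike train of
100-200 µV lasting at least 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import CHANNELS, graph_distances
from .io import EegEpoch

__all__ = [
    "SynthConfig",
    "DischargeTemplate",
    "TEMPLATE_KINDS",
    "DEFAULT_TYPE_COUNTS",
    "gen_fgn",
    "make_template",
    "gen_epoch",
    "gen_dataset",
]

#: The seven epileptiform discharge types.
TEMPLATE_KINDS: tuple[str, ...] = (
    "spike",
    "sharp",
    "spike_slow_wave",
    "sharp_slow_wave",
    "polyspike",
    "polyspike_slow_wave",
    "spike_rhythm",
)

#: Study-cohort class sizes: per-type discharge counts (sum 540).
DEFAULT_TYPE_COUNTS: dict[str, int] = {
    "spike": 69,
    "sharp": 82,
    "spike_slow_wave": 174,
    "sharp_slow_wave": 72,
    "polyspike": 64,
    "polyspike_slow_wave": 77,
    "spike_rhythm": 2,
}


@dataclass
class SynthConfig:
    """Generator parameters; the defaults are the package's study conditions.

    Hurst exponents: normal background near 0.6 (weakly persistent resting
    EEG), discharge background 0.75 (transient-laden epochs are more
    persistent); ``h_jitter`` is the between-epoch standard deviation.
    Amplitudes are in µV: 15 µV fGn background, 8/16 µV alpha rhythm
    (normal/discharge), doubled on O1/O2.  Planted templates decay as
    ``attenuation**d`` with scalp graph distance d from the focal set.
    """

    n_channels: int = 19
    fs: float = 256.0
    epoch_len: float = 4.0
    h_normal: float = 0.60
    h_discharge: float = 0.75
    h_jitter: float = 0.06
    bg_sd: float = 15.0
    alpha_amp_normal: float = 8.0
    alpha_amp_discharge: float = 16.0
    alpha_band: tuple[float, float] = (8.0, 13.0)
    occipital_gain: float = 2.0
    focal_channels: tuple[str, ...] = ("F7", "T3")
    attenuation: float = 0.4
    template_amplitude: float = 150.0
    polarity: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.h_normal < 1 and 0 < self.h_discharge < 1):
            raise ValueError("Hurst exponents must lie in (0, 1)")
        n = self.fs * self.epoch_len
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("fs * epoch_len must be a positive integer")
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must lie in (0, 1]")
        unknown = set(self.focal_channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown focal channels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))


@dataclass
class DischargeTemplate:
    """A sampled transient waveform of one discharge type."""

    kind: str
    duration_ms: float
    amplitude: float
    waveform: np.ndarray
    fs: float


def gen_fgn(
    h: float,
    n: int,
    sd: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    size: int = 1,
) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    Returns a (size, n) array (squeezed to 1-D when size == 1) of stationary
    Gaussian series with autocovariance
    gamma(k) = (sd^2/2) (|k+1|^{2h} - 2|k|^{2h} + |k-1|^{2h}).
    """
    if not 0 < h < 1:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {h}")
    if n < 2:
        raise ValueError(f"series length must be >= 2, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)

    g = 2.0 * h
    k = np.arange(n + 1, dtype=float)
    r = 0.5 * (np.abs(k + 1) ** g - 2 * k**g + np.abs(k - 1) ** g)
    circ = np.concatenate([r, r[-2:0:-1]])  # length 2n
    lam = np.fft.fft(circ).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative round-off eigenvalues

    m = 2 * n
    # independent complex noise in every bin with variance lam_k / m; the
    # real part of its DFT then has exactly the circulant covariance (each
    # bin contributes lam_k/m * cos(2*pi*k*d/m) at lag d, summing to gamma(d))
    a = rng.standard_normal((size, m))
    b = rng.standard_normal((size, m))
    spec = np.sqrt(lam / m) * (a + 1j * b)
    x = np.fft.fft(spec, axis=1).real[:, :n]
    out = sd * x
    return out[0] if size == 1 else out


def _bump(n: int, rise_frac: float = 0.35) -> np.ndarray:
    """Smooth asymmetric unit bump (fast rise, slower fall), min 0, max 1."""
    t = np.linspace(0.0, 1.0, n, endpoint=True)
    y = np.empty(n)
    a = rise_frac
    up = t <= a
    y[up] = 0.5 * (1 - np.cos(np.pi * t[up] / a))
    y[~up] = 0.5 * (1 + np.cos(np.pi * (t[~up] - a) / (1 - a)))
    return y


def _n_samples(duration_ms: float, fs: float) -> int:
    return int(round(duration_ms * fs / 1000.0))


def _scale(wave: np.ndarray, amplitude: float, polarity: int) -> np.ndarray:
    rng_ = wave.max() - wave.min()
    return polarity * amplitude * wave / rng_


_SPIKE_DUR = (20.0, 70.0)
_SHARP_DUR = (70.0, 200.0)
_SLOW_DUR = (200.0, 500.0)
_RHYTHM_FREQ = (10.0, 25.0)


def make_template(
    kind: str,
    fs: float = 256.0,
    *,
    duration_ms: float | None = None,
    amplitude: float | None = None,
    slow_duration_ms: float = 350.0,
    slow_amplitude: float | None = None,
    n_spikes: int = 3,
    freq: float = 15.0,
    rhythm_duration_s: float = 1.5,
    polarity: int = -1,
) -> DischargeTemplate:
    """Build one discharge-template waveform, validating clinical ranges.

    ``duration_ms`` refers to the spike/sharp component; composite kinds
    append a slow half-wave (or repeat spikes).  The peak-to-trough range of
    the returned waveform equals ``amplitude`` exactly for single transients
    and for each component of composites.
    """
    if kind not in TEMPLATE_KINDS:
        raise ValueError(f"unknown template kind: {kind!r}")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be -1 or +1")

    def spike_wave(dur: float, amp: float) -> np.ndarray:
        if not _SPIKE_DUR[0] <= dur <= _SPIKE_DUR[1]:
            raise ValueError(f"spike duration {dur} ms outside {_SPIKE_DUR}")
        if amp <= 50.0:
            raise ValueError(f"spike amplitude must exceed 50 µV, got {amp}")
        return _scale(_bump(_n_samples(dur, fs)), amp, polarity)

    def sharp_wave(dur: float, amp: float) -> np.ndarray:
        if not _SHARP_DUR[0] <= dur <= _SHARP_DUR[1]:
            raise ValueError(f"sharp duration {dur} ms outside {_SHARP_DUR}")
        if not 100.0 <= amp <= 200.0:
            raise ValueError(f"sharp amplitude {amp} µV outside [100, 200]")
        return _scale(_bump(_n_samples(dur, fs)), amp, polarity)

    def slow_wave(dur: float, amp: float) -> np.ndarray:
        if not _SLOW_DUR[0] <= dur <= _SLOW_DUR[1]:
            raise ValueError(f"slow-wave duration {dur} ms outside {_SLOW_DUR}")
        n = _n_samples(dur, fs)
        return _scale(np.sin(np.pi * np.linspace(0, 1, n)), amp, polarity)

    if kind == "spike":
        dur = 45.0 if duration_ms is None else duration_ms
        amp = 150.0 if amplitude is None else amplitude
        wave = spike_wave(dur, amp)
        total_ms = dur
    elif kind == "sharp":
        dur = 135.0 if duration_ms is None else duration_ms
        amp = 150.0 if amplitude is None else amplitude
        wave = sharp_wave(dur, amp)
        total_ms = dur
    elif kind in ("spike_slow_wave", "sharp_slow_wave"):
        fast = kind == "spike_slow_wave"
        dur = (45.0 if fast else 135.0) if duration_ms is None else duration_ms
        amp = 150.0 if amplitude is None else amplitude
        s_amp = amp if slow_amplitude is None else slow_amplitude
        head = spike_wave(dur, amp) if fast else sharp_wave(dur, amp)
        wave = np.concatenate([head, slow_wave(slow_duration_ms, s_amp)])
        total_ms = dur + slow_duration_ms
    elif kind in ("polyspike", "polyspike_slow_wave"):
        if n_spikes < 2:
            raise ValueError("a polyspike complex requires two or more spikes")
        dur = 45.0 if duration_ms is None else duration_ms
        amp = 150.0 if amplitude is None else amplitude
        one = spike_wave(dur, amp)
        wave = np.concatenate([one] * n_spikes)
        total_ms = dur * n_spikes
        if kind == "polyspike_slow_wave":
            s_amp = amp if slow_amplitude is None else slow_amplitude
            wave = np.concatenate([wave, slow_wave(slow_duration_ms, s_amp)])
            total_ms += slow_duration_ms
    else:  # spike_rhythm
        if not _RHYTHM_FREQ[0] <= freq <= _RHYTHM_FREQ[1]:
            raise ValueError(f"spike-rhythm frequency {freq} Hz outside {_RHYTHM_FREQ}")
        if rhythm_duration_s < 1.0:
            raise ValueError("a spike rhythm must last at least 1 s")
        amp = 150.0 if amplitude is None else amplitude
        if not 100.0 <= amp <= 200.0:
            raise ValueError(f"spike-rhythm amplitude {amp} µV outside [100, 200]")
        n_cycle = max(int(round(fs / freq)), 2)
        n_total = _n_samples(rhythm_duration_s * 1000.0, fs)
        cycle = _bump(n_cycle)
        reps = int(np.ceil(n_total / n_cycle))
        wave = _scale(np.tile(cycle, reps)[:n_total], amp, polarity)
        total_ms = rhythm_duration_s * 1000.0

    return DischargeTemplate(
        kind=kind, duration_ms=total_ms, amplitude=amp, waveform=wave, fs=fs
    )


def _template_for_label(label: str, config: SynthConfig, rng: np.random.Generator) -> DischargeTemplate:
    amp = config.template_amplitude
    if label in ("sharp", "sharp_slow_wave", "spike_rhythm"):
        amp = float(np.clip(amp, 100.0, 200.0))
    return make_template(
        label,
        fs=config.fs,
        amplitude=amp,
        polarity=config.polarity,
        freq=float(rng.uniform(12.0, 20.0)) if label == "spike_rhythm" else 15.0,
    )


def gen_epoch(
    label: str,
    config: SynthConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EegEpoch:
    """Generate one labeled epoch; discharge labels plant their template.

    The returned epoch's ``focal_channels`` is the ground-truth focal set
    (empty for normal epochs).
    """
    config = config or SynthConfig()
    if label != "normal" and label not in TEMPLATE_KINDS:
        raise ValueError(f"unknown label: {label!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    n = config.n_samples
    is_discharge = label != "normal"
    h_mean = config.h_discharge if is_discharge else config.h_normal
    h = float(np.clip(rng.normal(h_mean, config.h_jitter), 0.05, 0.95))

    signals = gen_fgn(h, n, sd=config.bg_sd, rng=rng, size=config.n_channels)

    # alpha rhythm: one frequency per epoch, random phase per channel
    f_alpha = rng.uniform(*config.alpha_band)
    t = np.arange(n) / config.fs
    amp = config.alpha_amp_discharge if is_discharge else config.alpha_amp_normal
    amps = np.full(config.n_channels, amp)
    for occ in ("O1", "O2"):
        amps[CHANNELS.index(occ)] *= config.occipital_gain
    phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
    signals = signals + amps[:, None] * np.sin(
        2 * np.pi * f_alpha * t[None, :] + phases[:, None]
    )

    focal: tuple[str, ...] = ()
    if is_discharge:
        template = _template_for_label(label, config, rng)
        wave = template.waveform
        if wave.shape[0] > n:
            wave = wave[:n]
        onset = int(rng.integers(0, n - wave.shape[0] + 1))
        dist = graph_distances(config.focal_channels)
        for name, d in dist.items():
            gain = config.attenuation**d
            signals[CHANNELS.index(name), onset : onset + wave.shape[0]] += gain * wave
        focal = tuple(config.focal_channels)

    return EegEpoch(
        signals=signals,
        fs=config.fs,
        channel_names=CHANNELS,
        label=label,
        focal_channels=focal,
    )


def gen_dataset(
    n_normal: int = 100,
    n_per_type: dict[str, int] | tuple[int, ...] | None = None,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> list[EegEpoch]:
    """Generate a shuffled labeled collection of epochs.

    ``n_per_type`` defaults to the study-cohort catalog (69 spikes, 82
    sharps, 174 spike-and-slow-wave, 72 sharp-and-slow-wave, 64 polyspike,
    77 polyspike-and-slow-wave, 2 spike rhythms; 540 discharges), paired
    with 100 normal controls for 640 epochs total.
    """
    config = config or SynthConfig()
    if n_per_type is None:
        counts = dict(DEFAULT_TYPE_COUNTS)
    elif isinstance(n_per_type, dict):
        counts = {k: int(v) for k, v in n_per_type.items()}
    else:
        counts = dict(zip(TEMPLATE_KINDS, n_per_type))
    if n_normal < 0 or any(v < 0 for v in counts.values()):
        raise ValueError("epoch counts must be non-negative")

    labels = ["normal"] * n_normal
    for kind in TEMPLATE_KINDS:
        labels.extend([kind] * counts.get(kind, 0))

    master = np.random.default_rng(config.seed if seed is None else seed)
    order = master.permutation(len(labels))
    child_seeds = np.random.SeedSequence(
        int(master.integers(0, 2**31 - 1))
    ).spawn(len(labels))
    epochs = [
        gen_epoch(labels[i], config, rng=np.random.default_rng(child_seeds[j]))
        for j, i in enumerate(order)
    ]
    return epochs
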