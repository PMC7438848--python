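"""EDF input/output, montage referencing, band-limiting and epoch segmentation.

The study conventions baked into the defaults: 256 Hz sampling, 0.1-70 Hz
analog bandwidth with a 50 Hz notch, average montage, and non-overlapping
4 s epochs of the 19-channel 10-20 montage.

EDF files are read through :mod:`mne` (imported lazily); writing uses a
minimal 16-bit EDF encoder implemented here.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .channels import CHANNELS, normalize_name

__all__ = [
    "Recording",
    "EegEpoch",
    "read_edf",
    "write_edf",
    "apply_reference",
    "filter_epoch",
    "segment_epochs",
]


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    ``signals`` is channel-by-sample; ``channel_names`` follows the canonical
    10-20 order after :func:`read_edf`.
    """

    signals: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channel-by-sample array")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match signal rows")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EegEpoch:
    """One fixed-length 19-channel epoch (µV) with an optional class label.

    ``focal_channels`` carries synthetic ground truth when the epoch came from
    the generator; it is None for epochs read from disk.
    """

    signals: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CHANNELS
    label: str | None = None
    focal_channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channel-by-sample array")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"expected {len(self.channel_names)} channels, got {self.signals.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file and return the 19 canonical channels in µV.

    Extra channels are ignored; any of the 19 required 10-20 names missing
    from the file raises a ``ValueError`` naming the absent channels.
    Channel-name matching is case/space-insensitive.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    mapping: dict[str, str] = {}
    for raw_name in raw.ch_names:
        canon = normalize_name(raw_name)
        if canon is not None and canon not in mapping:
            mapping[canon] = raw_name
    missing = [name for name in CHANNELS if name not in mapping]
    if missing:
        raise ValueError(f"EDF file is missing required channels: {', '.join(missing)}")
    data = raw.get_data(picks=[mapping[name] for name in CHANNELS])
    return Recording(signals=data * 1e6, fs=fs, channel_names=CHANNELS, reference="raw")


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: Recording | EegEpoch) -> None:
    """Write a recording as a 16-bit EDF file (one 1 s data record per second).

    The total length must be an integer number of seconds at ``fs``.  Each
    channel gets its own symmetric physical range so quantization error is at
    most half a step of (2 * max|x|) / 65534.
    """
    x = np.asarray(recording.signals, dtype=float)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = x.shape
    if n_samp % fs != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_rec = n_samp // fs

    dig_min, dig_max = -32767, 32767
    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-6)
    scale = phys_max / dig_max  # µV per digital unit
    digital = np.round(x / scale[:, None]).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_ascii("0", 8),
            _edf_ascii("X", 80),
            _edf_ascii("X", 80),
            _edf_ascii(now.strftime("%d.%m.%y"), 8),
            _edf_ascii(now.strftime("%H.%M.%S"), 8),
            _edf_ascii(256 * (1 + n_ch), 8),
            _edf_ascii("", 44),
            _edf_ascii(n_rec, 8),
            _edf_ascii(1, 8),
            _edf_ascii(n_ch, 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_edf_ascii(f"EEG {name}", 16) for name in recording.channel_names),
            b"".join(_edf_ascii("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_edf_ascii("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_ascii(f"{-p:.6g}"[:8], 8) for p in phys_max),
            b"".join(_edf_ascii(f"{p:.6g}"[:8], 8) for p in phys_max),
            b"".join(_edf_ascii(dig_min, 8) for _ in range(n_ch)),
            b"".join(_edf_ascii(dig_max, 8) for _ in range(n_ch)),
            b"".join(_edf_ascii("", 80) for _ in range(n_ch)),
            b"".join(_edf_ascii(fs, 8) for _ in range(n_ch)),
            b"".join(_edf_ascii("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        # data records: for each second, each channel's fs samples in sequence
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def quantization_step(recording: Recording | EegEpoch) -> np.ndarray:
    """Per-channel µV size of one 16-bit digital step for :func:`write_edf`."""
    x = np.asarray(recording.signals, dtype=float)
    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-6)
    return 2 * phys_max / (2 * 32767)


def apply_reference(recording: Recording, mode: str = "average") -> Recording:
    """Re-reference a recording.

    ``average`` subtracts the instantaneous mean across the 19 channels from
    every channel; ``raw`` (earlobe-referenced input) is a passthrough.
    """
    if mode == "raw":
        return Recording(
            signals=recording.signals.copy(),
            fs=recording.fs,
            channel_names=recording.channel_names,
            reference=recording.reference,
        )
    if mode == "average":
        mean = recording.signals.mean(axis=0, keepdims=True)
        return Recording(
            signals=recording.signals - mean,
            fs=recording.fs,
            channel_names=recording.channel_names,
            reference="average",
        )
    raise ValueError(f"unknown reference mode: {mode!r}")


def filter_epoch(
    epoch: EegEpoch,
    low: float = 0.1,
    high: float = 70.0,
    notch: float | None = 50.0,
    notch_q: float = 30.0,
) -> EegEpoch:
    """Zero-phase band-pass (4th-order Butterworth) plus optional notch.

    Forward-backward filtering preserves transient morphology, which the
    Signal Range statistic depends on.
    """
    fs = epoch.fs
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges: low={low}, high={high}, fs={fs}")
    if notch is not None and not (low < notch < high):
        raise ValueError(f"notch frequency {notch} must lie inside ({low}, {high})")
    sos = _sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = _sig.sosfiltfilt(sos, epoch.signals, axis=1)
    if notch is not None:
        b, a = _sig.iirnotch(notch, Q=notch_q, fs=fs)
        y = _sig.filtfilt(b, a, y, axis=1)
    return EegEpoch(
        signals=y,
        fs=fs,
        channel_names=epoch.channel_names,
        label=epoch.label,
        focal_channels=epoch.focal_channels,
    )


def segment_epochs(recording: Recording, epoch_len: float = 4.0) -> list[EegEpoch]:
    """Cut a recording into consecutive non-overlapping epochs.

    A trailing partial epoch is discarded; a recording shorter than one epoch
    raises.
    """
    n_epoch = int(round(epoch_len * recording.fs))
    if recording.n_samples < n_epoch:
        raise ValueError(
            f"recording of {recording.duration:.2f} s is shorter than one "
            f"{epoch_len} s epoch"
        )
    n = recording.n_samples // n_epoch
    return [
        EegEpoch(
            signals=recording.signals[:, k * n_epoch : (k + 1) * n_epoch].copy(),
            fs=recording.fs,
            channel_names=recording.channel_names,
        )
        for k in range(n)
    ]
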