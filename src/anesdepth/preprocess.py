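"""Raw EEG ingestion, band-pass filtering and epoching.

The monitoring pipeline operates on fixed-length epochs of a single EEG
channel.  Defaults: sampling rate 125 Hz and epoch length 500 samples, so
one epoch is 4 s — the typical update cadence of bedside depth monitors.
Band-pass default 0.5-47 Hz (Butterworth order 4, zero-phase) covers every
spectral band the feature set uses while excluding mains interference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "EpochedSignal",
    "DepthTrajectory",
    "bandpass_filter",
    "epoch_signal",
    "read_edf",
    "read_delimited",
    "write_delimited",
    "write_epochs",
    "read_epochs",
    "write_edf",
]

DEFAULT_FS = 125.0
DEFAULT_EPOCH_LEN = 500
DEFAULT_BAND = (0.5, 47.0)
DEFAULT_FILTER_ORDER = 4

PHASES = ("induction", "maintenance", "recovery")


@dataclass
class RawRecording:
    """Single-channel EEG trace in microvolts."""

    samples: np.ndarray
    fs: float
    subject_id: str = "S0"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a nonempty 1-d sequence")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples after ingestion")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class EpochedSignal:
    """Ordered fixed-length epochs cut from one recording."""

    epochs: np.ndarray  # (n_epochs, N)
    fs: float
    epoch_times: np.ndarray  # epoch start times, seconds
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a 2-d array (n_epochs, N)")
        if len(self.epoch_times) != len(self.epochs):
            raise ValueError("epoch_times length must match epoch count")
        if len(self.epoch_times) > 1 and not np.all(np.diff(self.epoch_times) > 0):
            raise ValueError("epoch_times must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[1]


@dataclass
class DepthTrajectory:
    """Reference / ground-truth depth index (0-100) with phase labels.

    Phases, when all present, form contiguous blocks in the order
    induction -> maintenance -> recovery.
    """

    times: np.ndarray
    depth: np.ndarray
    phase: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.times.shape != self.depth.shape:
            raise ValueError("times and depth must have equal length")
        if np.any(self.depth < 0) or np.any(self.depth > 100):
            raise ValueError("depth values must lie within [0, 100]")
        if self.phase is None:
            self.phase = np.full(self.times.shape, "maintenance", dtype=object)
        else:
            self.phase = np.asarray(self.phase, dtype=object)
            unknown = set(self.phase) - set(PHASES)
            if unknown:
                raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def depth_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the depth series at arbitrary times."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.depth)

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Nearest-sample phase label at arbitrary times."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float))
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.phase[idx]


def bandpass_filter(
    rec: RawRecording,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> RawRecording:
    """Zero-phase Butterworth band-pass.

    Forward-backward (``sosfiltfilt``) filtering keeps epoch timestamps
    aligned with the raw trace.  Length and sampling rate are preserved.
    """
    nyq = rec.fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < lo < hi < Nyquist ({nyq} Hz)"
        )
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=rec.fs, output="sos")
    # second-order sections are stable for any practical order; a NaN output
    # would indicate numerical breakdown at the requested order
    out = sps.sosfiltfilt(sos, rec.samples)
    if np.isnan(out).any():
        raise ValueError(f"filter unstable at order {order}")
    return RawRecording(out, rec.fs, rec.subject_id, rec.start_time)


def epoch_signal(
    rec: RawRecording, N: int = DEFAULT_EPOCH_LEN, overlap: int = 0
) -> EpochedSignal:
    """Cut a recording into epochs of exactly ``N`` samples.

    A trailing window shorter than ``N`` is discarded.  Number of epochs is
    ``floor((L - N) / (N - overlap)) + 1``.
    """
    L = rec.samples.size
    if N > L:
        raise ValueError(f"recording has {L} samples; at least {N} required")
    if not (0 <= overlap < N):
        raise ValueError(f"overlap must satisfy 0 <= overlap < N, got {overlap}")
    step = N - overlap
    n_epochs = (L - N) // step + 1
    idx = np.arange(n_epochs)[:, None] * step + np.arange(N)[None, :]
    times = rec.start_time + (np.arange(n_epochs) * step) / rec.fs
    return EpochedSignal(rec.samples[idx], rec.fs, times, rec.subject_id)


# ---------------------------------------------------------------------------
# readers / writers


def read_edf(path, channel: str | None = None, subject_id: str | None = None) -> RawRecording:
    """Read one channel of an EDF file.

    Takes the first EEG-typed channel unless ``channel`` names one.
    Values are returned in microvolts.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        picks = mne.pick_types(raw.info, eeg=True)
        if len(picks) == 0:
            picks = [0]
        channel = raw.ch_names[picks[0]]
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    if np.isnan(data).any():
        raise ValueError(f"channel {channel!r} contains NaN samples")
    sid = subject_id if subject_id is not None else str(path)
    return RawRecording(data, float(raw.info["sfreq"]), sid)


def read_delimited(path, subject_id: str | None = None) -> RawRecording:
    """Read a 2-column delimited text trace (time_s, amplitude_uV)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("delimited trace needs two columns: time_s, amplitude_uV")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("trace contains NaN amplitudes")
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time column must be uniformly sampled")
    sid = subject_id if subject_id is not None else str(path)
    return RawRecording(x, 1.0 / dt[0], sid, start_time=float(t[0]))


def write_delimited(rec: RawRecording, path) -> None:
    """Write a recording as a 2-column CSV (time_s, amplitude_uV)."""
    import pandas as pd

    pd.DataFrame({"time_s": rec.times, "amplitude_uV": rec.samples}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_epochs(ep: EpochedSignal, path) -> None:
    """Write an epoch table: epoch_index, sample_index, value."""
    import pandas as pd

    n, N = ep.epochs.shape
    pd.DataFrame(
        {
            "epoch_index": np.repeat(np.arange(n), N),
            "sample_index": np.tile(np.arange(N), n),
            "value": ep.epochs.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_epochs(path, fs: float, epoch_times=None, subject_id: str = "S0") -> EpochedSignal:
    """Read an epoch table written by :func:`write_epochs`."""
    import pandas as pd

    df = pd.read_csv(path)
    n = int(df["epoch_index"].max()) + 1
    N = int(df["sample_index"].max()) + 1
    values = df["value"].to_numpy(dtype=float).reshape(n, N)
    if epoch_times is None:
        epoch_times = np.arange(n) * (N / fs)
    return EpochedSignal(values, fs, epoch_times, subject_id)


def write_edf(rec: RawRecording, path, channel: str = "EEG Fpz-Cz") -> None:
    """Write a single-channel recording as EDF.

    Minimal EDF implementation: one signal, contiguous data records of 1 s,
    16-bit samples with per-file physical scaling.  No installed library
    exports EDF, so the format is produced directly; round-trips through
    :func:`read_edf`.
    """
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = rec.samples
    n_rec = len(x) // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    x = x[: n_rec * spr]
    pmin, pmax = float(np.min(x)), float(np.max(x))
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scaled = np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = scaled.astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),  # version
            pad(f"X X X {rec.subject_id}", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),  # header bytes: 256 + 256 per signal
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration, seconds
            pad("1", 4),  # number of signals
            # per-signal fields
            pad(channel, 16),
            pad("AgAgCl electrode", 80),
            pad("uV", 8),
            pad(f"{pmin:.8g}"[:8], 8),
            pad(f"{pmax:.8g}"[:8], 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),  # prefiltering
            pad(str(spr), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
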