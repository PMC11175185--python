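"""Filtering, normalization and segmentation of multi-channel sEMG recordings.

A continuous recording (per-sample gesture labels, 0 = rest) is high-pass
filtered, Z-scored with training-set statistics, cut into fixed-length
trials at label-run boundaries, and each trial is segmented into sliding
windows that feed the two model streams.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EmgRecording",
    "TrialSpec",
    "Trial",
    "WindowSpec",
    "NormalizerStats",
    "RawWindows",
    "DegenerateChannelError",
    "highpass_filter",
    "fit_normalizer",
    "zscore",
    "extract_trials",
    "slide_windows",
]


class DegenerateChannelError(ValueError):
    """Raised when a channel has zero variance and cannot be normalized."""


@dataclass
class EmgRecording:
    """Continuous multi-channel sEMG signal with per-sample annotations.

    Attributes
    ----------
    emg : (n_samples, n_channels) float array, raw signal units.
    stimulus : (n_samples,) int array; 0 during rest, gesture label (>=1)
        during an activation.
    repetition : (n_samples,) int array; repetition index of the ongoing
        activation, 0 during rest.
    fs : sampling rate in Hz.
    subject : subject identifier.
    """

    emg: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    fs: float
    subject: int = 0

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=np.float64)
        self.stimulus = np.asarray(self.stimulus).ravel().astype(np.int64)
        self.repetition = np.asarray(self.repetition).ravel().astype(np.int64)
        if self.emg.ndim != 2:
            raise ValueError("emg must be a 2-D samples x channels array")
        n = self.emg.shape[0]
        if self.stimulus.shape[0] != n or self.repetition.shape[0] != n:
            raise ValueError("stimulus/repetition length must match emg rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.emg.shape[1] < 1:
            raise ValueError("at least one channel required")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]


@dataclass(frozen=True)
class TrialSpec:
    """Fixed trial geometry: ``nt = fs * duration_s`` samples per trial."""

    nt: int
    duration_s: float
    fs: float

    @classmethod
    def from_duration(cls, duration_s: float, fs: float) -> "TrialSpec":
        nt = fs * duration_s
        if abs(nt - round(nt)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        return cls(nt=int(round(nt)), duration_s=duration_s, fs=fs)

    def __post_init__(self):
        if self.nt <= 0:
            raise ValueError("trial length must be positive")
        if abs(self.nt - self.fs * self.duration_s) > 1e-6:
            raise ValueError("nt must equal fs * duration_s")


@dataclass
class Trial:
    """One fixed-length gesture execution."""

    data: np.ndarray  # (nt, n_channels)
    label: int
    repetition: int
    subject: int
    padded: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D")
        if self.label < 1:
            raise ValueError("trial label must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry over one trial.

    ``n_windows = floor((nt - window_samples) / stride_samples) + 1``.
    """

    window_ms: float
    stride_ms: float
    window_samples: int
    stride_samples: int
    n_windows: int

    @classmethod
    def from_ms(cls, window_ms: float, fs: float, nt: int,
                stride_ms: float | None = None) -> "WindowSpec":
        """Build from millisecond sizes; stride defaults to the window."""
        if stride_ms is None:
            stride_ms = window_ms
        w = int(round(window_ms * fs / 1000.0))
        s = int(round(stride_ms * fs / 1000.0))
        if w < 1 or s < 1:
            raise ValueError("window and stride must be at least one sample")
        if w > nt:
            raise ValueError(f"window ({w} samples) longer than trial ({nt})")
        nf = (nt - w) // s + 1
        return cls(window_ms=window_ms, stride_ms=stride_ms,
                   window_samples=w, stride_samples=s, n_windows=nf)


@dataclass(frozen=True)
class NormalizerStats:
    """Per-channel mean and population standard deviation."""

    mu: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=np.float64))
        if np.any(self.delta <= 0):
            bad = int(np.flatnonzero(self.delta <= 0)[0])
            raise DegenerateChannelError(
                f"channel {bad} has non-positive standard deviation"
            )

    @property
    def n_channels(self) -> int:
        return self.mu.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mu) / self.delta

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=np.float64) * self.delta + self.mu


@dataclass
class RawWindows:
    """Per-trial stack of raw windows: (n_windows, window_samples, channels)."""

    data: np.ndarray
    label: int
    repetition: int
    subject: int
    spec: WindowSpec = field(repr=False, default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("raw windows must be 3-D")
        if self.spec is not None and self.data.shape[0] != self.spec.n_windows:
            raise ValueError("window count does not match spec")


# ---------------------------------------------------------------------------


def highpass_filter(recording: EmgRecording, cutoff: float = 1.0,
                    order: int = 2) -> EmgRecording:
    """Zero-phase Butterworth high-pass filter, applied channel-wise.

    Forward-backward (``sosfiltfilt``) application keeps features aligned
    with the label stream.
    """
    nyquist = recording.fs / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, cutoff, btype="highpass", fs=recording.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, recording.emg, axis=0)
    return EmgRecording(emg=filtered, stimulus=recording.stimulus,
                        repetition=recording.repetition, fs=recording.fs,
                        subject=recording.subject)


def fit_normalizer(train_data) -> NormalizerStats:
    """Fit per-channel Z-score statistics over a collection of matrices.

    Uses the population standard deviation (ddof=0). Fit on training data
    only, then apply to validation data, to avoid leakage.
    """
    if isinstance(train_data, np.ndarray):
        train_data = [train_data]
    stacked = np.concatenate([np.asarray(m, dtype=np.float64) for m in train_data],
                             axis=0)
    if stacked.shape[0] < 2:
        raise ValueError("need at least two samples per channel")
    mu = stacked.mean(axis=0)
    delta = stacked.std(axis=0, ddof=0)
    if np.any(delta == 0):
        bad = int(np.flatnonzero(delta == 0)[0])
        raise DegenerateChannelError(f"channel {bad} is constant (zero variance)")
    return NormalizerStats(mu=mu, delta=delta)


def zscore(recording: EmgRecording, stats: NormalizerStats) -> EmgRecording:
    """Apply ``z = (x - mu) / delta`` channel-wise to a recording."""
    if stats.n_channels != recording.n_channels:
        raise ValueError(
            f"stats cover {stats.n_channels} channels, recording has "
            f"{recording.n_channels}"
        )
    return EmgRecording(emg=stats.transform(recording.emg),
                        stimulus=recording.stimulus,
                        repetition=recording.repetition,
                        fs=recording.fs, subject=recording.subject)


def _label_runs(stimulus: np.ndarray):
    """Yield (start, stop, label) for contiguous nonzero runs (half-open)."""
    changes = np.flatnonzero(np.diff(stimulus) != 0) + 1
    boundaries = np.concatenate(([0], changes, [stimulus.shape[0]]))
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if stimulus[lo] != 0:
            yield int(lo), int(hi), int(stimulus[lo])


def extract_trials(recording: EmgRecording, spec: TrialSpec) -> list[Trial]:
    """Cut one trial per contiguous nonzero label run.

    Runs longer than ``spec.nt`` are truncated to their first ``nt``
    samples; shorter runs are zero-padded at the end and flagged.
    """
    trials: list[Trial] = []
    for lo, hi, label in _label_runs(recording.stimulus):
        run = recording.emg[lo:hi]
        rep = int(recording.repetition[lo:hi].max())
        padded = False
        if run.shape[0] >= spec.nt:
            data = run[:spec.nt]
        else:
            pad = np.zeros((spec.nt - run.shape[0], recording.n_channels))
            data = np.concatenate([run, pad], axis=0)
            padded = True
        trials.append(Trial(data=data, label=label, repetition=rep,
                            subject=recording.subject, padded=padded))
    if not trials:
        warnings.warn("recording contains no nonzero labels; no trials extracted")
    return trials


def slide_windows(trial: Trial, wspec: WindowSpec) -> RawWindows:
    """Segment a trial into ``wspec.n_windows`` windows at fixed stride."""
    nt = trial.data.shape[0]
    w, s = wspec.window_samples, wspec.stride_samples
    if w > nt:
        raise ValueError(f"window ({w}) longer than trial ({nt})")
    nf = (nt - w) // s + 1
    idx = np.arange(nf)[:, None] * s + np.arange(w)[None, :]
    data = trial.data[idx]  # (nf, w, channels)
    return RawWindows(data=data, label=trial.label, repetition=trial.repetition,
                      subject=trial.subject, spec=wspec)
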