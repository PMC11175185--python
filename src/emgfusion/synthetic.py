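"""Synthetic multi-channel sEMG generator with known class structure.

The signal model is amplitude-modulated band-limited Gaussian noise: each
activation is carrier noise scaled per channel by a class-specific envelope
(with a trapezoidal onset/offset ramp), superimposed on baseline noise.
Per-sample stimulus/repetition vectors mirror the layout of real
acquisition files so the same trial extractor serves both paths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocessing import EmgRecording, Trial, TrialSpec, extract_trials

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "default_envelopes",
    "generate_recording",
    "generate_dataset",
]


def default_envelopes(n_classes: int, n_channels: int,
                      separation: float = 2.0,
                      base: float = 1.0) -> np.ndarray:
    """Well-separated per-class per-channel gains.

    Each class boosts its own subset of channels by ``separation``, so class
    pairs differ by at least that factor on some channel.
    """
    env = np.full((n_classes, n_channels), base, dtype=np.float64)
    for cls in range(n_classes):
        env[cls, cls % n_channels::n_classes] *= separation
    return env


@dataclass
class SyntheticConfig:
    n_classes: int
    n_repetitions: int
    n_channels: int = 10
    fs: float = 100.0
    active_duration: float = 5.0
    rest_duration: float = 3.0
    envelope_amplitudes: np.ndarray | None = None
    carrier_band: tuple[float, float] = (10.0, 45.0)
    noise_sd: float = 0.05
    ramp_duration: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.active_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        lo, hi = self.carrier_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("carrier_band must satisfy 0 < low < high < fs/2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.envelope_amplitudes is None:
            self.envelope_amplitudes = default_envelopes(self.n_classes,
                                                         self.n_channels)
        self.envelope_amplitudes = np.asarray(self.envelope_amplitudes,
                                              dtype=np.float64)
        if self.envelope_amplitudes.shape != (self.n_classes, self.n_channels):
            raise ValueError("envelope_amplitudes must be n_classes x n_channels")
        if np.any(self.envelope_amplitudes < 0):
            raise ValueError("envelope amplitudes must be non-negative")

    @property
    def active_samples(self) -> int:
        return int(round(self.active_duration * self.fs))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.fs))


def _trapezoid(n: int, ramp: int) -> np.ndarray:
    env = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[-ramp:] = np.linspace(1.0, 0.0, ramp + 1)[1:]
    return env


def _band_limited_noise(rng: np.random.Generator, n: int, channels: int,
                        band: tuple[float, float], fs: float) -> np.ndarray:
    white = rng.standard_normal((n, channels))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, white, axis=0)
    sd = carrier.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return carrier / sd


def generate_recording(config: SyntheticConfig, subject_id: int = 0) -> EmgRecording:
    """Generate one continuous recording for one subject.

    Activations are laid out class-major: for each class, ``n_repetitions``
    activations of ``active_duration * fs`` samples, each preceded and the
    last followed by a rest span.  Stimulus is 0 at rest and the 1-based
    class index during activation; repetition carries the 1-based
    repetition counter.  A fixed (seed, subject) pair is bit-reproducible.
    """
    rng = np.random.default_rng([config.seed, subject_id])
    na, nr = config.active_samples, config.rest_samples
    n_blocks = config.n_classes * config.n_repetitions
    total = nr + n_blocks * (na + nr)

    emg = config.noise_sd * rng.standard_normal((total, config.n_channels))
    stimulus = np.zeros(total, dtype=np.int64)
    repetition = np.zeros(total, dtype=np.int64)
    ramp = _trapezoid(na, int(round(config.ramp_duration * config.fs)))

    cursor = nr
    for cls in range(1, config.n_classes + 1):
        gains = config.envelope_amplitudes[cls - 1]
        for rep in range(1, config.n_repetitions + 1):
            carrier = _band_limited_noise(rng, na, config.n_channels,
                                          config.carrier_band, config.fs)
            emg[cursor:cursor + na] += carrier * ramp[:, None] * gains[None, :]
            stimulus[cursor:cursor + na] = cls
            repetition[cursor:cursor + na] = rep
            cursor += na + nr
    return EmgRecording(emg=emg, stimulus=stimulus, repetition=repetition,
                        fs=config.fs, subject=subject_id)


def generate_dataset(config: SyntheticConfig, n_subjects: int,
                     split_rule: tuple[set[int], set[int]],
                     ) -> tuple[list[Trial], list[Trial]]:
    """Generate trials for several subjects and split by repetition index.

    `split_rule` is a pair of disjoint 1-based repetition-index sets
    (train, validation); trials are routed strictly by their repetition.
    """
    train_reps, val_reps = (set(split_rule[0]), set(split_rule[1]))
    if train_reps & val_reps:
        raise ValueError(f"split sets overlap: {sorted(train_reps & val_reps)}")
    if not val_reps:
        warnings.warn("validation repetition set is empty")
    spec = TrialSpec.from_duration(config.active_duration, config.fs)
    train: list[Trial] = []
    val: list[Trial] = []
    for subject in range(n_subjects):
        recording = generate_recording(config, subject_id=subject)
        for trial in extract_trials(recording, spec):
            if trial.repetition in train_reps:
                train.append(trial)
            elif trial.repetition in val_reps:
                val.append(trial)
    logger.info("generated %d train / %d validation trials for %d subjects",
                len(train), len(val), n_subjects)
    return train, val
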