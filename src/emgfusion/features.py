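"""Time-domain feature extraction: MAV, ZC, SSC, WL, RMS per window per channel.

Scalar operations accept one window of one channel (a 1-D vector);
`build_feature_tensor` evaluates all five features over every window and
channel of a trial, producing a (n_windows, 5, n_channels) tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import RawWindows

__all__ = [
    "FEATURE_ORDER",
    "FeatureConfig",
    "FeatureTensor",
    "mav",
    "zc",
    "ssc",
    "wl",
    "rms",
    "build_feature_tensor",
]

FEATURE_ORDER: tuple[str, ...] = ("MAV", "ZC", "SSC", "WL", "RMS")


@dataclass(frozen=True)
class FeatureConfig:
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self):
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if len(self.feature_order) != 5 or len(set(self.feature_order)) != 5:
            raise ValueError("feature_order must list the five features once each")
        if set(self.feature_order) != set(FEATURE_ORDER):
            raise ValueError(f"feature_order must be a permutation of {FEATURE_ORDER}")


@dataclass
class FeatureTensor:
    """Per-trial feature stack of shape (n_windows, 5, n_channels)."""

    data: np.ndarray
    label: int
    repetition: int
    subject: int
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1] != 5:
            raise ValueError("feature tensor must be (n_windows, 5, n_channels)")


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("window must be a non-empty 1-D vector")
    return x


def rms(x) -> float:
    """Root mean square: sqrt(mean(x^2))."""
    x = _as_window(x)
    return float(np.sqrt(np.mean(x**2)))


def mav(x) -> float:
    """Mean absolute value: mean(|x|)."""
    x = _as_window(x)
    return float(np.mean(np.abs(x)))


def wl(x) -> float:
    """Waveform length: sum of absolute first differences."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("waveform length needs at least two samples")
    return float(np.sum(np.abs(np.diff(x))))


def zc(x, threshold: float = 0.0) -> int:
    """Zero crossings: adjacent sign changes with amplitude gap >= threshold."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("zero crossing needs at least two samples")
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= threshold
    return int(np.count_nonzero(sign_change & big_enough))


def ssc(x, threshold: float = 0.0) -> int:
    """Slope sign changes: interior points where (x_i-x_{i-1})(x_i-x_{i+1}) >= threshold."""
    x = _as_window(x)
    if x.size < 3:
        raise ValueError("slope sign change needs at least three samples")
    product = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(product >= threshold))


def build_feature_tensor(windows: RawWindows,
                         config: FeatureConfig | None = None) -> FeatureTensor:
    """Compute all five features for every window and channel, vectorized.

    Output layout: ``data[w, f, c]`` with features in ``config.feature_order``.
    """
    if config is None:
        config = FeatureConfig()
    x = windows.data  # (nf, k, c)
    if x.shape[1] < 3:
        raise ValueError("windows must hold at least three samples for SSC")

    computed = {
        "MAV": np.mean(np.abs(x), axis=1),
        "RMS": np.sqrt(np.mean(x**2, axis=1)),
        "WL": np.sum(np.abs(np.diff(x, axis=1)), axis=1),
        "ZC": np.count_nonzero(
            (x[:, :-1] * x[:, 1:] < 0)
            & (np.abs(x[:, :-1] - x[:, 1:]) >= config.zc_threshold),
            axis=1,
        ).astype(np.float64),
        "SSC": np.count_nonzero(
            (x[:, 1:-1] - x[:, :-2]) * (x[:, 1:-1] - x[:, 2:])
            >= config.ssc_threshold,
            axis=1,
        ).astype(np.float64),
    }
    data = np.stack([computed[name] for name in config.feature_order], axis=1)
    return FeatureTensor(data=data, label=windows.label,
                         repetition=windows.repetition,
                         subject=windows.subject, config=config)
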