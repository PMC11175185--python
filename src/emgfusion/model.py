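"""Dual-stream fusion network and its single-stream ablation.

Both models process a sequence of analysis windows. The dual-stream model
runs two per-window encoders — a convolutional stack on the five
time-domain features and a convolutional stack with an inner recurrent
layer on the raw samples — concatenates their flattened outputs, and feeds
the window sequence through two bidirectional LSTM layers and a dense head
with a per-window softmax.

`lstm_cell_step` is an independent, equation-level single-step oracle used
to verify the vectorized recurrent layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, concatenate, conv_output_length

__all__ = [
    "ModelSpec",
    "ModelGraph",
    "RecurrentCellSpec",
    "LayerShape",
    "db1_spec",
    "desk_spec",
    "DB1_REFERENCE_TRACE",
    "build_dual_stream",
    "build_single_stream",
    "lstm_cell_step",
    "shape_trace",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture description with valid-mode shape arithmetic."""

    n_windows: int = 25
    window_samples: int = 20
    n_channels: int = 10
    n_features: int = 5
    n_classes: int = 52
    conv_filters: int = 256
    feature_conv_kernels: tuple[int, int] = (3, 2)
    feature_conv_strides: tuple[int, int] = (1, 1)
    raw_conv_kernels: tuple[int, int] = (2, 2)
    raw_conv_strides: tuple[int, int] = (2, 2)
    raw_inner_units: int = 256
    bilstm_units_per_direction: int = 100
    dense_units: int = 512
    conv_dropout: float = 0.3
    dense_dropout: float = 0.5
    l2_coefficient: float = 0.01
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.9

    def feature_lengths(self) -> list[int]:
        """Per-window lengths through the feature-stream convs."""
        lengths = [self.n_features]
        for k, s in zip(self.feature_conv_kernels, self.feature_conv_strides):
            lengths.append(conv_output_length(lengths[-1], k, s))
        return lengths

    def raw_lengths(self) -> list[int]:
        lengths = [self.window_samples]
        for k, s in zip(self.raw_conv_kernels, self.raw_conv_strides):
            lengths.append(conv_output_length(lengths[-1], k, s))
        return lengths

    @property
    def feature_flat_width(self) -> int:
        return self.feature_lengths()[-1] * self.conv_filters

    @property
    def raw_flat_width(self) -> int:
        return self.raw_lengths()[-1] * self.conv_filters

    @property
    def fused_width(self) -> int:
        return self.feature_flat_width + self.raw_flat_width

    def validate(self) -> None:
        self.feature_lengths()
        self.raw_lengths()
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


def db1_spec(**overrides) -> ModelSpec:
    """The published full-scale configuration (52 classes, 256 filters)."""
    return ModelSpec(**overrides)


def desk_spec(n_classes: int = 5, **overrides) -> ModelSpec:
    """Reduced configuration that trains in minutes on one CPU."""
    defaults = dict(
        n_classes=n_classes,
        conv_filters=32,
        raw_inner_units=32,
        bilstm_units_per_direction=32,
        dense_units=64,
        conv_dropout=0.1,
        dense_dropout=0.2,
        l2_coefficient=1e-4,
    )
    defaults.update(overrides)
    return ModelSpec(**defaults)


@dataclass(frozen=True)
class LayerShape:
    name: str
    shape: tuple[int, ...]


# Published layer geometry of the full DB1 dual-stream model (window
# dimension x per-window shape, batch axis omitted).
DB1_REFERENCE_TRACE: tuple[LayerShape, ...] = (
    LayerShape("input/features", (25, 5, 10)),
    LayerShape("input/raw", (25, 20, 10)),
    LayerShape("conv1/features", (25, 3, 256)),
    LayerShape("conv1/raw", (25, 10, 256)),
    LayerShape("lstm/raw", (25, 10, 256)),
    LayerShape("conv2/features", (25, 2, 256)),
    LayerShape("conv2/raw", (25, 5, 256)),
    LayerShape("flatten/features", (25, 512)),
    LayerShape("flatten/raw", (25, 1280)),
    LayerShape("concatenate", (25, 1792)),
    LayerShape("bilstm1", (25, 200)),
    LayerShape("bilstm2", (25, 200)),
    LayerShape("flatten", (25, 200)),
    LayerShape("dense1", (25, 512)),
    LayerShape("dense2", (25, 52)),
)


class _ConvBlock(nn.Module):
    def __init__(self, in_channels, filters, kernel, stride, dropout, spec,
                 rng):
        self.conv = nn.Conv1D(in_channels, filters, kernel, stride, rng)
        self.bn = nn.BatchNorm(filters, eps=spec.bn_epsilon,
                               momentum=spec.bn_momentum)
        self.act = nn.Activation("relu")
        self.drop = nn.Dropout(dropout)

    def forward(self, x, training=False, rng=None, **_):
        x = self.conv(x)
        x = self.bn(x, training=training)
        x = self.act(x)
        return self.drop(x, training=training, rng=rng)


class _Head(nn.Module):
    """Shared sequence head: two Bi-LSTMs, dense+BN+ReLU+dropout, softmax dense."""

    def __init__(self, in_width, spec: ModelSpec, rng):
        u = spec.bilstm_units_per_direction
        self.bilstm1 = nn.Bidirectional(in_width, u, rng)
        self.bilstm2 = nn.Bidirectional(2 * u, u, rng)
        self.dense1 = nn.Dense(2 * u, spec.dense_units, rng)
        self.bn = nn.BatchNorm(spec.dense_units, eps=spec.bn_epsilon,
                               momentum=spec.bn_momentum)
        self.act = nn.Activation("relu")
        self.drop = nn.Dropout(spec.dense_dropout)
        self.dense2 = nn.Dense(spec.dense_units, spec.n_classes, rng)

    def forward(self, x, training=False, rng=None, trace=None, **_):
        x = self.bilstm1(x)
        _record(trace, "bilstm1", x)
        x = self.bilstm2(x)
        _record(trace, "bilstm2", x)
        _record(trace, "flatten", x)  # shape-preserving marker
        x = self.dense1(x)
        x = self.bn(x, training=training)
        x = self.act(x)
        x = self.drop(x, training=training, rng=rng)
        _record(trace, "dense1", x)
        x = self.dense2(x)
        _record(trace, "dense2", x)
        return x


def _record(trace, name, x: Tensor):
    if trace is not None:
        trace.append(LayerShape(name, tuple(x.shape[1:])))


def _flatten_windows(x: Tensor) -> Tensor:
    b, nf, length, ch = x.shape
    return x.reshape(b, nf, length * ch)


class DualStreamModel(nn.Module):
    input_kinds = ("features", "raw")

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        f = spec.conv_filters
        fk, fs = spec.feature_conv_kernels, spec.feature_conv_strides
        rk, rs = spec.raw_conv_kernels, spec.raw_conv_strides
        self.feat_block1 = _ConvBlock(spec.n_channels, f, fk[0], fs[0],
                                      spec.conv_dropout, spec, rng)
        self.feat_block2 = _ConvBlock(f, f, fk[1], fs[1],
                                      spec.conv_dropout, spec, rng)
        self.raw_block1 = _ConvBlock(spec.n_channels, f, rk[0], rs[0],
                                     spec.conv_dropout, spec, rng)
        self.raw_lstm = nn.LSTM(f, spec.raw_inner_units, rng)
        self.raw_block2 = _ConvBlock(spec.raw_inner_units, f, rk[1], rs[1],
                                     spec.conv_dropout, spec, rng)
        self.head = _Head(spec.fused_width, spec, rng)

    def forward(self, features: Tensor, raw: Tensor, training=False,
                rng=None, trace=None, **_) -> Tensor:
        _record(trace, "input/features", features)
        _record(trace, "input/raw", raw)
        ft = self.feat_block1(features, training=training, rng=rng)
        rw = self.raw_block1(raw, training=training, rng=rng)
        _record(trace, "conv1/features", ft)
        _record(trace, "conv1/raw", rw)
        # inner recurrence runs over the within-window sample axis
        b, nf, length, ch = rw.shape
        rw = self.raw_lstm(rw.reshape(b * nf, length, ch))
        rw = rw.reshape(b, nf, length, self.raw_lstm.units)
        _record(trace, "lstm/raw", rw)
        ft = self.feat_block2(ft, training=training, rng=rng)
        rw = self.raw_block2(rw, training=training, rng=rng)
        _record(trace, "conv2/features", ft)
        _record(trace, "conv2/raw", rw)
        ft = _flatten_windows(ft)
        rw = _flatten_windows(rw)
        _record(trace, "flatten/features", ft)
        _record(trace, "flatten/raw", rw)
        fused = concatenate([ft, rw], axis=-1)
        _record(trace, "concatenate", fused)
        return self.head(fused, training=training, rng=rng, trace=trace)


class SingleStreamModel(nn.Module):
    """Ablation: raw windows through one conv stage, then the same head."""

    input_kinds = ("raw",)

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        f = spec.conv_filters
        rk, rs = spec.raw_conv_kernels, spec.raw_conv_strides
        self.raw_block = _ConvBlock(spec.n_channels, f, rk[0], rs[0],
                                    spec.conv_dropout, spec, rng)
        conv_len = conv_output_length(spec.window_samples, rk[0], rs[0])
        self.head = _Head(conv_len * f, spec, rng)

    def forward(self, raw: Tensor, training=False, rng=None, trace=None,
                **_) -> Tensor:
        _record(trace, "input/raw", raw)
        x = self.raw_block(raw, training=training, rng=rng)
        _record(trace, "conv1/raw", x)
        x = _flatten_windows(x)
        _record(trace, "flatten/raw", x)
        return self.head(x, training=training, rng=rng, trace=trace)


@dataclass
class ModelGraph:
    """A realized model plus its verified layer-shape trace."""

    model: nn.Module
    spec: ModelSpec
    trace: list[LayerShape] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.model.parameters()))

    def probe_inputs(self, batch: int = 1) -> tuple[Tensor, ...]:
        s = self.spec
        shapes = {
            "features": (batch, s.n_windows, s.n_features, s.n_channels),
            "raw": (batch, s.n_windows, s.window_samples, s.n_channels),
        }
        return tuple(Tensor(np.zeros(shapes[k])) for k in self.model.input_kinds)


def shape_trace(graph: ModelGraph, batch: int = 1) -> list[LayerShape]:
    """Realized per-layer output shapes (batch axis omitted) on a probe."""
    trace: list[LayerShape] = []
    graph.model.forward(*graph.probe_inputs(batch), trace=trace)
    return trace


def build_dual_stream(spec: ModelSpec, seed: int = 0) -> ModelGraph:
    rng = np.random.default_rng(seed)
    graph = ModelGraph(model=DualStreamModel(spec, rng), spec=spec)
    graph.trace = shape_trace(graph)
    return graph


def build_single_stream(spec: ModelSpec, seed: int = 0) -> ModelGraph:
    rng = np.random.default_rng(seed)
    graph = ModelGraph(model=SingleStreamModel(spec, rng), spec=spec)
    graph.trace = shape_trace(graph)
    return graph


# ---------------------------------------------------------------------------
# Single-step recurrent-cell oracle


@dataclass
class RecurrentCellSpec:
    """Explicit per-gate LSTM weights in standard form.

    Input kernels ``w_*`` are (input_size, units), recurrent kernels
    ``u_*`` are (units, units), biases are (units,).  Gates use the
    logistic sigmoid; candidate and cell output use tanh.
    """

    w_c: np.ndarray
    u_c: np.ndarray
    b_c: np.ndarray
    w_i: np.ndarray
    u_i: np.ndarray
    b_i: np.ndarray
    w_f: np.ndarray
    u_f: np.ndarray
    b_f: np.ndarray
    w_o: np.ndarray
    u_o: np.ndarray
    b_o: np.ndarray

    def __post_init__(self):
        units = self.w_c.shape[1]
        for name in ("c", "i", "f", "o"):
            w, u, b = (getattr(self, f"w_{name}"), getattr(self, f"u_{name}"),
                       getattr(self, f"b_{name}"))
            if w.shape[1] != units or u.shape != (units, units) or b.shape != (units,):
                raise ValueError(f"inconsistent shapes for gate {name!r}")

    @classmethod
    def from_lstm_layer(cls, layer: "nn.LSTM") -> "RecurrentCellSpec":
        """Split a vectorized layer's stacked (i, f, g, o) kernels per gate."""
        u = layer.units
        wx, wh, b = layer.w_x.data, layer.w_h.data, layer.bias.data
        blocks = {g: slice(k * u, (k + 1) * u)
                  for k, g in enumerate(("i", "f", "c", "o"))}
        kwargs = {}
        for g, sl in blocks.items():
            kwargs[f"w_{g}"] = wx[:, sl].copy()
            kwargs[f"u_{g}"] = wh[:, sl].copy()
            kwargs[f"b_{g}"] = b[sl].copy()
        return cls(**kwargs)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def lstm_cell_step(cell: RecurrentCellSpec, x_t: np.ndarray,
                   h_prev: np.ndarray, c_prev: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step written directly from the gate equations.

    candidate = tanh(x W_c + h_prev U_c + b_c)
    i, f, o   = sigmoid(x W_g + h_prev U_g + b_g)
    c_t = f * c_prev + i * candidate;  h_t = o * tanh(c_t)
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=np.float64))
    if x_t.shape[1] != cell.w_c.shape[0]:
        raise ValueError("input width does not match cell weights")
    candidate = np.tanh(x_t @ cell.w_c + h_prev @ cell.u_c + cell.b_c)
    i_gate = _sigmoid(x_t @ cell.w_i + h_prev @ cell.u_i + cell.b_i)
    f_gate = _sigmoid(x_t @ cell.w_f + h_prev @ cell.u_f + cell.b_f)
    o_gate = _sigmoid(x_t @ cell.w_o + h_prev @ cell.u_o + cell.b_o)
    c_t = f_gate * c_prev + i_gate * candidate
    h_t = o_gate * np.tanh(c_t)
    return h_t, c_t
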