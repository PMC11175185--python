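"""Neural-network layers built on the autodiff engine.

Conventions follow channels-last sequence layout: a stream tensor is
(batch, windows, length, channels) and per-window vectors are
(batch, windows, width).  Convolutions are valid-mode only.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Module",
    "Dense",
    "Conv1D",
    "BatchNorm",
    "Activation",
    "Dropout",
    "LSTM",
    "Bidirectional",
    "Adam",
    "conv_output_length",
]


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-mode output length; raises if the geometry does not tile."""
    if kernel > length:
        raise ValueError(f"kernel {kernel} longer than input {length}")
    if (length - kernel) % stride != 0:
        raise ValueError(
            f"conv geometry invalid: length {length}, kernel {kernel}, "
            f"stride {stride} leaves a partial window"
        )
    return (length - kernel) // stride + 1


class Module:
    """Base class: parameter collection and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def regularization_params(self) -> list[Tensor]:
        """Parameters subject to the L2 kernel penalty (kernels only)."""
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                params.extend(value.regularization_params())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.regularization_params())
        return params

    def __call__(self, x, **kwargs):
        return self.forward(x, **kwargs)


class Dense(Module):
    """Affine map on the last axis."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_features + units))
        self.weight = Tensor(rng.uniform(-limit, limit, (in_features, units)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(units), requires_grad=True)
        self.units = units

    def regularization_params(self) -> list[Tensor]:
        return [self.weight]

    def forward(self, x: Tensor, **_) -> Tensor:
        return x @ self.weight + self.bias


class Conv1D(Module):
    """Valid-mode 1-D convolution over the length axis (axis -2).

    Implemented as a sum of strided slices times per-tap weight matrices,
    so it broadcasts over any leading axes (time-distributed for free).
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = in_channels * kernel
        limit = np.sqrt(6.0 / (fan_in + filters))
        self.weight = Tensor(rng.uniform(-limit, limit, (kernel, in_channels, filters)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(filters), requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.filters = filters

    def regularization_params(self) -> list[Tensor]:
        return [self.weight]

    def forward(self, x: Tensor, **_) -> Tensor:
        length = x.shape[-2]
        out_len = conv_output_length(length, self.kernel, self.stride)
        span = (out_len - 1) * self.stride + 1
        out = None
        for tap in range(self.kernel):
            sl = x[..., tap:tap + span:self.stride, :] @ self.weight[tap]
            out = sl if out is None else out + sl
        return out + self.bias


class BatchNorm(Module):
    """Batch normalization over all axes except the last (channel) axis."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor, training: bool = False, **_) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            norm = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta


class Activation(Module):
    def __init__(self, kind: str):
        if kind not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x: Tensor, **_) -> Tensor:
        return x.relu() if self.kind == "relu" else x.tanh()


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: Tensor, training: bool = False,
                rng: np.random.Generator | None = None, **_) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask

class LSTM(Module):
    """Standard LSTM over axis -2 of a (batch, time, features) tensor.

    Gate blocks are stored stacked in order (input, forget, candidate,
    output): w_x is (features, 4*units), w_h is (units, 4*units).
    """

    GATE_ORDER = ("i", "f", "g", "o")

    def __init__(self, input_size: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        limit = np.sqrt(6.0 / (input_size + units))
        self.w_x = Tensor(rng.uniform(-limit, limit, (input_size, 4 * units)),
                          requires_grad=True)
        rlimit = np.sqrt(6.0 / (units + units))
        self.w_h = Tensor(rng.uniform(-rlimit, rlimit, (units, 4 * units)),
                          requires_grad=True)
        bias = np.zeros(4 * units)
        bias[units:2 * units] = 1.0  # forget-gate bias init
        self.bias = Tensor(bias, requires_grad=True)
        self.units = units
        self.return_sequences = return_sequences

    def forward(self, x: Tensor, **_) -> Tensor:
        batch, steps, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((batch, u)))
        c = Tensor(np.zeros((batch, u)))
        outputs: list[Tensor] = []
        for t in range(steps):
            z = x[:, t, :] @ self.w_x + h @ self.w_h + self.bias
            i = z[:, 0 * u:1 * u].sigmoid()
            f = z[:, 1 * u:2 * u].sigmoid()
            g = z[:, 2 * u:3 * u].tanh()
            o = z[:, 3 * u:4 * u].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h.reshape(batch, 1, u))
        if self.return_sequences:
            return concatenate(outputs, axis=1)
        return outputs[-1].reshape(batch, u)


class Bidirectional(Module):
    """Run two LSTMs forward and backward in time; concatenate features."""

    def __init__(self, input_size: int, units_per_direction: int,
                 rng: np.random.Generator):
        self.forward_layer = LSTM(input_size, units_per_direction, rng)
        self.backward_layer = LSTM(input_size, units_per_direction, rng)
        self.units = 2 * units_per_direction

    def forward(self, x: Tensor, **_) -> Tensor:
        fwd = self.forward_layer(x)
        bwd = self.backward_layer(x[:, ::-1, :])[:, ::-1, :]
        return concatenate([fwd, bwd], axis=-1)


class Adam:
    """Adam optimizer with optional decoupled-from-loss L2 kernel penalty."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 l2: float = 0.0, l2_params: list[Tensor] | None = None):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.l2 = l2
        self._l2_ids = {id(p) for p in (l2_params or [])}
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for idx, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2 and id(p) in self._l2_ids:
                g = g + 2.0 * self.l2 * p.data
            self.m[idx] = self.beta1 * self.m[idx] + (1 - self.beta1) * g
            self.v[idx] = self.beta2 * self.v[idx] + (1 - self.beta2) * g * g
            m_hat = self.m[idx] / (1 - self.beta1**self.t)
            v_hat = self.v[idx] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
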