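"""Neural-network layers built on the autograd engine.

Weight initialization follows the adversarial-translation convention:
convolution kernels drawn from N(0, 0.02), instance-norm scale 1 / offset 0.
Every layer takes an explicit ``numpy.random.Generator`` so construction is
fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: recursive parameter discovery and flat state dicts."""

    def parameters(self) -> list[Tensor]:
        params = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for name, value in vars(self).items():
            _collect_named(value, f"{prefix}{name}", state)
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = ""):
        own = self.named_state(prefix)
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for name, param in _iter_named_params(self, prefix):
            param.data = np.asarray(state[name], dtype=np.float32)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x):
        return self.forward(x)


def _collect(value):
    if isinstance(value, Tensor):
        return [value] if value.requires_grad else []
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, name, state):
    if isinstance(value, Tensor) and value.requires_grad:
        state[name] = value.data
    elif isinstance(value, Module):
        state.update(value.named_state(prefix=name + "."))
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _collect_named(v, f"{name}.{i}", state)


def _iter_named_params(module: "Module", prefix: str = ""):
    """Yield (name, Tensor) pairs with names matching :meth:`Module.named_state`."""

    def walk(value, name):
        if isinstance(value, Tensor):
            if value.requires_grad:
                yield name, value
        elif isinstance(value, Module):
            for sub, v in vars(value).items():
                yield from walk(v, f"{name}.{sub}")
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                yield from walk(v, f"{name}.{i}")

    for attr, value in vars(module).items():
        yield from walk(value, f"{prefix}{attr}")


class Conv(Module):
    def __init__(self, dims: int, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, pad_mode: str = "zeros",
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        shape = (out_channels, in_channels) + (kernel,) * dims
        self.weight = Tensor(rng.normal(0.0, 0.02, shape), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding, self.pad_mode = stride, padding, pad_mode

    def forward(self, x):
        return ag.conv(x, self.weight, self.bias, self.stride, self.padding, self.pad_mode)


class ConvTranspose(Module):
    def __init__(self, dims: int, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 2, padding: int = 1, output_padding: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        shape = (in_channels, out_channels) + (kernel,) * dims
        self.weight = Tensor(rng.normal(0.0, 0.02, shape), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x):
        return ag.conv_transpose(x, self.weight, self.bias, self.stride,
                                 self.padding, self.output_padding)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes, with affine."""

    def __init__(self, channels: int, dims: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels) + (1,) * dims), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels) + (1,) * dims), requires_grad=True)
        self.eps = eps
        self.dims = dims

    def forward(self, x):
        axes = tuple(range(2, 2 + self.dims))
        mu = x.mean(axis=axes, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=axes, keepdims=True)
        xhat = centered * ag.power(var + self.eps, -0.5)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        self.negative_slope = negative_slope

    def forward(self, x):
        return ag.leaky_relu(x, self.negative_slope)


class Tanh(Module):
    def forward(self, x):
        return ag.tanh(x)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock(Module):
    """Two 3x3 convolutions with instance norm; identity shortcut added pre-activation."""

    def __init__(self, dims: int, channels: int, pad_mode: str = "reflect",
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv(dims, channels, channels, 3, 1, 1, pad_mode, rng=rng)
        self.norm1 = InstanceNorm(channels, dims)
        self.conv2 = Conv(dims, channels, channels, 3, 1, 1, pad_mode, rng=rng)
        self.norm2 = InstanceNorm(channels, dims)

    def forward(self, x):
        h = ag.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h
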