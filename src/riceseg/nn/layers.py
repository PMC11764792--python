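"""Module system: parameter containers and the layers the network is built from."""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Identity", "Linear", "Conv2d",
    "LayerNorm", "Dropout", "trunc_normal_",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad construction


def trunc_normal_(rng: np.random.Generator, shape, std: float = 0.02, dtype=np.float32) -> np.ndarray:
    """Normal(0, std) resampled into [-2 std, 2 std]."""
    vals = rng.normal(0.0, std, size=shape)
    bad = np.abs(vals) > 2 * std
    while bad.any():
        vals[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(vals) > 2 * std
    return vals.astype(dtype)


class Module:
    def __init__(self):
        self.training = True

    # -- containers -----------------------------------------------------------
    def _children(self):
        def walk(name, value):
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield from walk(f"{name}.{i}", m)

        for name, value in self.__dict__.items():
            yield from walk(name, value)

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield (prefix + name, value)
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, child in self._children():
            yield from child.named_modules(prefix + name + ".")

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.data.copy()) for k, v in self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(unexpected)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal_(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = F.matmul(x, self.weight)
        if self.bias is not None:
            y = F.add(y, self.bias)
        return y


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        fan_out = kernel_size * kernel_size * out_channels // groups
        std = math.sqrt(2.0 / fan_out)
        w = rng.normal(0.0, std, size=(out_channels, in_channels // groups, kernel_size, kernel_size))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding,
            dilation=self.dilation, groups=self.groups,
        )


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    Carries its own generator so a run is reproducible after
    :meth:`reseed` regardless of batch composition.
    """

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = float(p)
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)
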