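"""Learnable layers built on the autodiff backend.

All feature maps flow through these layers in the internal ``(C, B, H, W)``
layout.  Weights are initialised from a uniform fan-in scheme,
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``, drawn from a seeded generator so that
a model build is fully reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

DTYPE = np.float32


class Module:
    """Lightweight container: tracks parameters and sub-modules."""

    def parameters(self) -> Iterator[Tensor]:
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def named_arrays(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        """All state (parameters and buffers) as named numpy arrays."""
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield key, value.data
            elif isinstance(value, np.ndarray):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_arrays(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_arrays(f"{key}.{i}.")

    def load_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                value.data = np.asarray(arrays[key], dtype=value.data.dtype)
            elif isinstance(value, np.ndarray):
                value[...] = arrays[key]
            elif isinstance(value, Module):
                value.load_arrays(arrays, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_arrays(arrays, f"{key}.{i}.")

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int, dtype=DTYPE):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2dMix(Module):
    """Channel-mixing convolution with a ``kh x kw`` footprint, same-padding.

    Covers the strip convolutions (``1 x k`` and ``k x 1``), the point-wise
    (1x1) projections, and the 3x3 spatial-attention filter.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kh: int,
        kw: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=DTYPE,
    ):
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"kernel ({kh}x{kw}) must be odd for symmetric padding")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kh, self.kw = kh, kw
        fan_in = in_channels * kh * kw
        self.weight = T.tensor(
            _uniform_fan_in(rng, (out_channels, in_channels, kh, kw), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            T.tensor(_uniform_fan_in(rng, (out_channels,), fan_in, dtype), requires_grad=True)
            if bias
            else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        C, _, H, W = x.shape
        if self.kw > W:
            raise ValueError(f"time kernel {self.kw} exceeds time axis {W}")
        if self.kh > H:
            raise ValueError(f"space kernel {self.kh} exceeds electrode axis {H}")
        return T.conv_mix(x, self.weight, self.bias, self.kh, self.kw)


class ChannelConv1d(Module):
    """Single shared 1-D filter along the channel axis (bias-free)."""

    def __init__(self, k: int = 3, rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = k
        self.weight = T.tensor(_uniform_fan_in(rng, (k,), k, dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv1d_channel(x, self.weight)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=DTYPE):
        self.gamma = T.tensor(np.ones((channels, 1, 1, 1), dtype), requires_grad=True)
        self.beta = T.tensor(np.zeros((channels, 1, 1, 1), dtype), requires_grad=True)
        self.running_mean = np.zeros((channels, 1, 1, 1), dtype)
        self.running_var = np.ones((channels, 1, 1, 1), dtype)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return T.batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=DTYPE,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = T.tensor(
            _uniform_fan_in(rng, (in_features, out_features), in_features, dtype),
            requires_grad=True,
        )
        self.bias = T.tensor(
            _uniform_fan_in(rng, (out_features,), in_features, dtype), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.weight), self.bias)


def set_training(module: Module, training: bool) -> None:
    """Flip train/eval mode on every BatchNorm in a module tree."""
    for value in vars(module).values():
        if isinstance(value, BatchNorm2d):
            value.training = training
        elif isinstance(value, Module):
            set_training(value, training)
        elif isinstance(value, (list, tuple)):
            for item in value:
                if isinstance(item, Module):
                    set_training(item, training)
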