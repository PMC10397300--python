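"""Trainable layers built on the autograd engine.

Weight initialization is He-style fan-in scaling drawn from a seedable
``numpy.random.Generator``; every layer takes the generator explicitly so a
model build is a pure function of (config, seed).
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter traversal, train/eval mode, state export."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterable["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def parameters(self) -> List[Tensor]:
        out, seen = [], set()

        def walk(m: Module):
            for v in m.__dict__.values():
                items = v if isinstance(v, (list, tuple)) else [v]
                for u in items:
                    if isinstance(u, Tensor) and u.requires_grad and id(u) not in seen:
                        seen.add(id(u))
                        out.append(u)
                    elif isinstance(u, Module) and id(u) not in seen:
                        seen.add(id(u))
                        walk(u)

        walk(self)
        return out

    def buffers(self) -> List[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out, seen = [], set()

        def walk(m: Module):
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean, m.running_var])
            for c in m._children():
                if id(c) not in seen:
                    seen.add(id(c))
                    walk(c)

        walk(self)
        return out

    def train(self, flag: bool = True):
        self.training = flag
        for c in self._children():
            c.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def he_init(rng: np.random.Generator, shape, fan_in: int, slope: float = 0.0) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + slope * slope))
    std = gain / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int | tuple,
        stride: int = 1,
        groups: int = 1,
        rng: Optional[np.random.Generator] = None,
        slope: float = 0.01,
    ):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide in ({in_channels}) and out ({out_channels}) channels"
            )
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Tensor(
            he_init(rng, (out_channels, in_channels // groups, kh, kw), fan_in, slope),
            requires_grad=True,
        )
        self.stride = stride
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, stride=self.stride, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2d(x, self.kernel, self.stride)


class LocalResponseNorm(Module):
    def __init__(self, t: float = 2.0, alpha: float = 1e-4, beta: float = 0.75, n: int = 5):
        super().__init__()
        self.t, self.alpha, self.beta, self.n = t, alpha, beta, n

    def forward(self, x: Tensor) -> Tensor:
        return ag.local_response_norm(x, self.t, self.alpha, self.beta, self.n)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(he_init(rng, (in_features, out_features), in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class GlobalAvgPool(Module):
    """Spatial global average pooling: (B, C, H, W) -> (B, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.mean(x, (2, 3))


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
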