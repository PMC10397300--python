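"""Optimizers for the autograd engine: Adam (default) and SGD+momentum."""

from __future__ import annotations

from typing import List

import numpy as np

from .autograd import Tensor


class Optimizer:
    def __init__(self, params: List[Tensor], lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)


class SGD(Optimizer):
    def __init__(self, params, lr=1e-3, momentum=0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= self.lr * b


def make_optimizer(name: str, params, lr: float, momentum: float = 0.9) -> Optimizer:
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr, momentum=momentum)
    raise ValueError(f"unknown optimizer {name!r}")
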