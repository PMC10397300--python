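"""Self-contained numeric primitives: softmax head, Leaky ReLU, local
response normalization and global pooling.

These are plain-numpy, batch-agnostic functions.  They preserve the input
floating dtype (float64 in, float64 out), which makes them suitable as the
reference path checked against explicit-loop oracles; the training engine in
:mod:`burnganext.autograd` reuses the same definitions.

Feature tensors follow the channels-first layout ``(C, H, W)`` (or
``(B, C, H, W)`` with a leading batch axis); the channel axis is always
``-3``.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

__all__ = [
    "LRNParams",
    "softmax",
    "leaky_relu",
    "local_response_norm",
    "global_pool",
]


@dataclasses.dataclass(frozen=True)
class LRNParams:
    """Constants of the divisive cross-channel normalization.

    ``t`` is the additive constant in the denominator, ``alpha`` scales the
    squared-activation sum, ``beta`` is the denominator exponent and ``n`` the
    total channel-neighborhood size (``n // 2`` channels on each side).
    Defaults are the canonical AlexNet setting.
    """

    t: float = 2.0
    alpha: float = 1e-4
    beta: float = 0.75
    n: int = 5
    #: stage names after whose output the normalization is applied
    stages: tuple = ("conv1", "conv2")

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("LRN neighborhood size n must be >= 1")
        if self.beta < 0:
            raise ValueError("LRN exponent beta must be >= 0")
        if self.t <= 0 and self.alpha <= 0:
            raise ValueError("LRN denominator must be positive: need t > 0 or alpha > 0")


def softmax(phi: np.ndarray, axis: int = -1) -> np.ndarray:
    """Convert logits to probabilities, stabilized by max-subtraction.

    Rows along ``axis`` are non-negative and sum to one.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(phi)):
        raise ValueError("softmax input must be finite")
    z = phi - phi.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """Identity for non-negative entries, ``slope * x`` for negative ones."""
    if not 0.0 <= slope < 1.0:
        raise ValueError(f"leaky_relu slope must lie in [0, 1), got {slope}")
    x = np.asarray(x)
    return np.where(x >= 0, x, x * slope)


def _sliding_channel_sum(x: np.ndarray, half: int, axis: int) -> np.ndarray:
    """Sum of a sliding window of size ``2*half + 1`` along ``axis``,
    truncated at the edges (equivalently, zero-padded)."""
    n = x.shape[axis]
    out = x.copy()

    def sl(a, b):
        idx = [slice(None)] * x.ndim
        idx[axis] = slice(a, b)
        return tuple(idx)

    for off in range(1, min(half, n - 1) + 1):
        out[sl(off, None)] += x[sl(None, n - off)]
        out[sl(None, n - off)] += x[sl(off, None)]
    return out


def local_response_norm(a: np.ndarray, params: Optional[LRNParams] = None) -> np.ndarray:
    """Divisive normalization across a sliding channel neighborhood.

    Each activation ``a[i]`` at a spatial position is divided by
    ``(t + alpha * sum_j a[j]**2) ** beta`` where ``j`` runs over the
    channels ``max(0, i - n//2) .. min(C-1, i + n//2)``.
    """
    params = params or LRNParams()
    params.validate()
    a = np.asarray(a)
    if a.ndim < 3:
        raise ValueError("expected a (C, H, W) or (B, C, H, W) feature tensor")
    a64 = a.astype(np.float64, copy=False)
    ssq = _sliding_channel_sum(a64 * a64, params.n // 2, axis=a.ndim - 3)
    denom = (params.t + params.alpha * ssq) ** params.beta
    out = a64 / denom
    return out.astype(a.dtype, copy=False) if a.dtype.kind == "f" else out


def global_pool(x: np.ndarray, mode: str = "avg", axis: str = "spatial") -> np.ndarray:
    """Global average / max pooling over the spatial or the channel axis.

    ``axis='spatial'`` collapses H and W, producing a per-channel vector
    (shape ``(..., C)``); ``axis='channel'`` collapses C keeping a singleton
    channel axis, producing a ``(..., 1, H, W)`` map.
    """
    x = np.asarray(x)
    if x.ndim < 3:
        raise ValueError("expected a (C, H, W) or (B, C, H, W) feature tensor")
    if mode not in ("avg", "max"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    if axis == "spatial":
        if x.shape[-1] == 0 or x.shape[-2] == 0:
            raise ValueError("cannot pool over an empty spatial extent")
        return x.mean(axis=(-2, -1)) if mode == "avg" else x.max(axis=(-2, -1))
    if axis == "channel":
        if x.shape[-3] == 0:
            raise ValueError("cannot pool over an empty channel extent")
        return (
            x.mean(axis=-3, keepdims=True)
            if mode == "avg"
            else x.max(axis=-3, keepdims=True)
        )
    raise ValueError(f"unknown pooling axis {axis!r}")
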