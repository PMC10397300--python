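"""A small reverse-mode automatic-differentiation engine over numpy arrays.

The network in :mod:`burnganext.model` is built from the primitives below:
each returns a :class:`Tensor` whose ``_backward`` closure propagates the
upstream gradient to its parents.  Convolution and pooling use
``sliding_window_view`` (im2col) so the heavy lifting happens inside BLAS
matmuls; the scatter in their backward passes loops only over the k*k window
offsets.

Convolutions use "same" padding with ceil-mode downsampling: the output
spatial size is ``ceil(in / stride)`` regardless of kernel size, which keeps
the 100 -> 50 -> 25 -> 13 -> 7 -> 4 trace of the network well defined.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .ops import _sliding_channel_sum

__all__ = ["Tensor", "backward"]


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable] = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _from_op(data, parents: Sequence[Tensor], backward_fn: Callable) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def backward(loss: Tensor) -> None:
    """Accumulate ``grad`` on every ``requires_grad`` leaf reachable from
    ``loss``.  Intermediate gradients and graph edges are released as soon
    as they have been consumed."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is None or node.grad is None:
            continue
        grads = node._backward(node.grad)
        for parent, g in zip(node._parents, grads):
            if g is None or not parent.requires_grad:
                continue
            parent.grad = g if parent.grad is None else parent.grad + g
        node.grad = None
        node._backward = None
        node._parents = ()


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / shape primitives
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _from_op(out, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def bw(g):
        ga = _unbroadcast(g * b.data, a.data.shape) if a.requires_grad else None
        gb = _unbroadcast(g * a.data, b.data.shape) if b.requires_grad else None
        return ga, gb

    return _from_op(out, (a, b), bw)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    """``x @ w`` with ``w`` 2-D and ``x`` of shape ``(..., F)``."""
    out = x.data @ w.data

    def bw(g):
        gx = g @ w.data.T if x.requires_grad else None
        if w.requires_grad:
            f = x.data.reshape(-1, x.data.shape[-1])
            gw = f.T @ g.reshape(-1, g.shape[-1])
        else:
            gw = None
        return gx, gw

    return _from_op(out, (x, w), bw)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    return _from_op(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def mean(x: Tensor, axes, keepdims: bool = False) -> Tensor:
    axes = tuple(axes) if isinstance(axes, (tuple, list)) else (axes,)
    out = x.data.mean(axis=axes, keepdims=keepdims)
    count = int(np.prod([x.data.shape[a] for a in axes]))

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g, x.data.shape) / count,)

    return _from_op(out, (x,), bw)


def sum_(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.data.shape).copy(),)

    return _from_op(out, (x,), bw)


def amax(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    idx = np.argmax(x.data, axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out = np.squeeze(out, axis=axis)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
        return (gx,)

    return _from_op(out, (x,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _from_op(out, tuple(tensors), bw)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = x.data[sl]

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        return (gx,)

    return _from_op(out, (x,), bw)


def index_channels(x: Tensor, perm: np.ndarray) -> Tensor:
    """Permute the channel axis (axis 1) by ``perm``."""
    inv = np.argsort(perm)
    out = x.data[:, perm]
    return _from_op(out, (x,), lambda g: (g[:, inv],))


def rot90(x: Tensor, k: int) -> Tensor:
    """Rotate the two trailing (spatial) axes by ``k`` quarter turns."""
    out = np.rot90(x.data, k, axes=(-2, -1)).copy()
    return _from_op(out, (x,), lambda g: (np.rot90(g, -k, axes=(-2, -1)).copy(),))


def sigmoid(x: Tensor) -> Tensor:
    out = expit(x.data)
    return _from_op(out, (x,), lambda g: (g * out * (1.0 - out),))


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    return _from_op(out, (x,), lambda g: (g * (x.data > 0),))


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    dtype = x.data.dtype if x.data.dtype.kind == "f" else np.float64
    factor = np.where(x.data < 0, dtype.type(slope), dtype.type(1))
    out = x.data * factor
    return _from_op(out, (x,), lambda g: (g * factor,))


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def same_pad(size: int, k: int, stride: int) -> Tuple[int, int, int]:
    """Ceil-mode 'same' padding: output size, pad-before, pad-after."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return out, total // 2, total - total // 2


def _im2col(xd: np.ndarray, kh: int, kw: int, stride: int, groups: int, pad_value=0.0):
    B, C, H, W = xd.shape
    OH, pt, pb = same_pad(H, kh, stride)
    OW, pl, pr = same_pad(W, kw, stride)
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=pad_value)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cg = C // groups
    # (B, C, OH, OW, kh, kw) -> (B, g, L, cg*kh*kw)
    cols = (
        win.reshape(B, groups, cg, OH, OW, kh, kw)
        .transpose(0, 1, 3, 4, 2, 5, 6)
        .reshape(B, groups, OH * OW, cg * kh * kw)
    )
    return cols, (OH, OW, pt, pl, xp.shape)


def conv2d_forward(xd: np.ndarray, wd: np.ndarray, stride: int = 1, groups: int = 1):
    """Grouped 2-D convolution with ceil-mode same padding (pure numpy).

    ``xd``: (B, C, H, W); ``wd``: (Cout, C/groups, kh, kw).  Returns
    ``(out, cache)`` where ``cache`` feeds the backward pass.  Pointwise
    (1x1, stride-1) convolutions skip im2col and run as batched matmuls.
    """
    B, C, H, W = xd.shape
    Cout, cg, kh, kw = wd.shape
    if C % groups or Cout % groups or cg != C // groups:
        raise ValueError("channel counts incompatible with the group count")
    og = Cout // groups
    if kh == 1 and kw == 1 and stride == 1:
        xr = xd.reshape(B, groups, cg, H * W)
        wR = wd.reshape(groups, og, cg)
        out = np.matmul(wR, xr).reshape(B, Cout, H, W)
        return out, ("pointwise", xr, (B, C, H, W), (Cout, cg, kh, kw), groups)
    cols, geom = _im2col(xd, kh, kw, stride, groups)
    OH, OW = geom[0], geom[1]
    wR = wd.reshape(groups, og, cg * kh * kw)
    out = np.matmul(cols, wR.transpose(0, 2, 1))  # (B, g, L, og)
    out = out.transpose(0, 1, 3, 2).reshape(B, Cout, OH, OW)
    return out, ("general", cols, geom, (B, C, H, W), (Cout, cg, kh, kw), stride, groups)


def conv2d_backward(g: np.ndarray, wd: np.ndarray, cache, need_x: bool, need_w: bool):
    gw = gx = None
    if cache[0] == "pointwise":
        _, xr, xshape, wshape, groups = cache
        B, C, H, W = xshape
        Cout, cg = wshape[0], wshape[1]
        og = Cout // groups
        dO = g.reshape(B, groups, og, H * W)
        if need_w:
            gw = np.einsum("bgol,bgcl->goc", dO, xr, optimize=True)
            gw = gw.reshape(Cout, cg, 1, 1)
        if need_x:
            wR = wd.reshape(groups, og, cg)
            gx = np.matmul(wR.transpose(0, 2, 1), dO).reshape(B, C, H, W)
        return gx, gw
    _, cols, geom, xshape, wshape, stride, groups = cache
    B, C, H, W = xshape
    Cout, cg, kh, kw = wshape
    OH, OW, pt, pl, xp_shape = geom
    og = Cout // groups
    dO = g.reshape(B, groups, og, OH * OW).transpose(0, 1, 3, 2)  # (B, g, L, og)
    if need_w:
        gw = np.einsum("bglf,bglo->gfo", cols, dO, optimize=True)
        gw = gw.transpose(0, 2, 1).reshape(Cout, cg, kh, kw)
    if need_x:
        wR = wd.reshape(groups, og, cg * kh * kw)
        dcols = np.matmul(dO, wR)  # (B, g, L, cg*kh*kw)
        dwin = (
            dcols.reshape(B, groups, OH, OW, cg, kh, kw)
            .transpose(0, 1, 4, 2, 3, 5, 6)
            .reshape(B, C, OH, OW, kh, kw)
        )
        gxp = np.zeros(xp_shape, dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i: i + stride * OH: stride, j: j + stride * OW: stride] += dwin[
                    :, :, :, :, i, j
                ]
        gx = gxp[:, :, pt: pt + H, pl: pl + W]
    return gx, gw


def conv2d(x: Tensor, w: Tensor, stride: int = 1, groups: int = 1) -> Tensor:
    out, cache = conv2d_forward(x.data, w.data, stride, groups)

    def bw(g):
        return conv2d_backward(g, w.data, cache, x.requires_grad, w.requires_grad)

    return _from_op(out, (x, w), bw)


def maxpool2d(x: Tensor, k: int, stride: int) -> Tensor:
    xd = x.data
    B, C, H, W = xd.shape
    OH, pt, pb = same_pad(H, k, stride)
    OW, pl, pr = same_pad(W, k, stride)
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win.reshape(B, C, OH, OW, k * k)  # copies
    idx = np.argmax(win, axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        # scatter each window's gradient to its argmax position in the
        # padded input via one bincount over global flat indices
        Hp, Wp = xp.shape[2], xp.shape[3]
        di, dj = np.divmod(idx, k)
        ri = di + (np.arange(OH) * stride)[None, None, :, None]
        rj = dj + (np.arange(OW) * stride)[None, None, None, :]
        base = (
            np.arange(B)[:, None, None, None] * C + np.arange(C)[None, :, None, None]
        ) * (Hp * Wp)
        flat = base + ri * Wp + rj
        acc = np.bincount(flat.ravel(), weights=g.ravel(), minlength=B * C * Hp * Wp)
        gxp = acc.reshape(B, C, Hp, Wp).astype(g.dtype, copy=False)
        return (gxp[:, :, pt: pt + H, pl: pl + W],)

    return _from_op(out, (x,), bw)


# ---------------------------------------------------------------------------
# normalization / loss
# ---------------------------------------------------------------------------

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    xd = x.data
    B, C, H, W = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[:, None, None]) * inv_std[:, None, None]
    out = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

    def bw(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3)) if gamma.requires_grad else None
        gbeta = g.sum(axis=(0, 2, 3)) if beta.requires_grad else None
        if not x.requires_grad:
            return None, ggamma, gbeta
        dxhat = g * gamma.data[:, None, None]
        if training:
            m = B * H * W
            s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
            gx = (inv_std[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        else:
            gx = dxhat * inv_std[:, None, None]
        return gx, ggamma, gbeta

    return _from_op(out, (x, gamma, beta), bw)


def local_response_norm(x: Tensor, t: float, alpha: float, beta_exp: float, n: int) -> Tensor:
    a = x.data
    half = n // 2
    ssq = _sliding_channel_sum(a * a, half, axis=1)
    denom = t + alpha * ssq
    dpow = denom ** (-beta_exp)
    out = a * dpow

    def bw(g):
        u = g * a * (dpow / denom)
        gx = g * dpow - (2.0 * alpha * beta_exp) * a * _sliding_channel_sum(u, half, axis=1)
        return (gx.astype(g.dtype, copy=False),)

    return _from_op(out, (x,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over the batch; labels are int codes."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    B = p.shape[0]
    ll = -np.log(np.maximum(p[np.arange(B), labels], 1e-12))
    loss = ll.mean()

    def bw(g):
        gp = p.copy()
        gp[np.arange(B), labels] -= 1.0
        return (g * gp / B,)

    return _from_op(np.asarray(loss), (logits,), bw)
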