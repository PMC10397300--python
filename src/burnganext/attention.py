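"""Residual, channel and spatial attention.

The residual attention module partitions a feature map into N groups of
C/N channels, each split into S = 4 subgroups.  After a channel shuffle that
interleaves group and subgroup indices, subgroup ``s`` is rotated by ``s``
quarter turns and passed through a shared 3x3 convolution K; the rotated
responses for s > 0 are gated by the unrotated response (Hadamard product)
and the results concatenated.

Channel attention derives per-channel gates from spatially pooled statistics
through shared fully connected layers (squeeze-excitation style); the gated
groups are summed, so the channel-attended map has C/N channels.  Spatial
attention stacks the channel-wise average and max maps, reduces them with a
3x3 convolution and gates every position with a sigmoid.

Two API levels are provided: plain-numpy functions operating on single
``(C, H, W)`` feature tensors (the reference path, dtype-preserving), and
autograd layers used inside the network.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autograd as ag
from .autograd import Tensor, conv2d_forward
from .config import AttentionConfig
from .errors import ConfigurationError, InputError
from .layers import Conv2d, Linear, Module

__all__ = [
    "shuffle_permutation",
    "channel_shuffle",
    "rotate_subgroup",
    "residual_attention_block",
    "channel_attention",
    "apply_channel_attention",
    "spatial_descriptor",
    "spatial_attention",
    "AttentionBlock",
]


# ---------------------------------------------------------------------------
# functional reference path (numpy, single feature tensor)
# ---------------------------------------------------------------------------

def shuffle_permutation(channels: int, n_groups: int, subgroups: int) -> np.ndarray:
    """The (N, S) transpose-interleave channel permutation."""
    if n_groups * subgroups == 0 or channels % (n_groups * subgroups):
        raise ConfigurationError(
            f"N*S = {n_groups}*{subgroups} must divide the channel count {channels}"
        )
    return (
        np.arange(channels)
        .reshape(n_groups, subgroups, -1)
        .transpose(1, 0, 2)
        .ravel()
    )


def channel_shuffle(x: np.ndarray, n_groups: int, subgroups: int) -> np.ndarray:
    """Permute channels so subgroup indices interleave across groups."""
    x = np.asarray(x)
    perm = shuffle_permutation(x.shape[-3], n_groups, subgroups)
    return np.take(x, perm, axis=x.ndim - 3)


def rotate_subgroup(x: np.ndarray, r: int) -> np.ndarray:
    """Rotate the spatial map by ``r`` quarter turns (r in 0..3).

    The rotation acts about the grid center on the two trailing axes;
    channels are untouched.
    """
    x = np.asarray(x)
    if not 0 <= r < 4:
        raise InputError(f"rotation index r must lie in 0..3, got {r}")
    if x.shape[-2] != x.shape[-1]:
        raise InputError(f"rotation needs a square spatial map, got {x.shape[-2:]}")
    return np.rot90(x, r, axes=(-2, -1)).copy()


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 (or any) stride-1 same-padded convolution of a (C, H, W) map."""
    out, _ = conv2d_forward(x[None], w, stride=1, groups=1)
    return out[0]


def residual_attention_block(
    x: np.ndarray, kernel: np.ndarray, config: Optional[AttentionConfig] = None
) -> np.ndarray:
    """Shared-kernel rotation/gating composition over the S subgroups.

    ``x`` is one feature group of C/N channels; ``kernel`` is the shared 3x3
    convolution weight of shape (Cs, Cs, 3, 3) where Cs = C/(N*S).  Subgroup
    ``s`` is rotated by ``s`` quarter turns and convolved; for s > 0 the
    response is gated by the s = 0 response.
    """
    config = config or AttentionConfig()
    s_count = config.subgroups
    x = np.asarray(x)
    c = x.shape[0]
    if c % s_count:
        raise InputError(f"subgroup count {s_count} does not divide {c} channels")
    cs = c // s_count
    if kernel.shape[0] != cs or kernel.shape[1] != cs:
        raise InputError(
            f"shared kernel maps {kernel.shape[1]} -> {kernel.shape[0]} channels, expected {cs}"
        )
    subgroups = [x[s * cs: (s + 1) * cs] for s in range(s_count)]
    y0 = _conv_same(rotate_subgroup(subgroups[0], 0), kernel)
    ys = [y0]
    for s in range(1, s_count):
        r = s % 4
        ys.append(_conv_same(rotate_subgroup(subgroups[s], r), kernel) * y0)
    return np.concatenate(ys, axis=0)


def channel_attention(
    group: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Per-channel gates for one group: sigmoid(FC(relu(FC(GAP(G))))).

    Returns a vector of length C/N with entries strictly in (0, 1); the FC
    weights are shared across groups by the caller.
    """
    group = np.asarray(group)
    if group.shape[-1] == 0 or group.shape[-2] == 0:
        raise InputError("cannot pool an empty spatial extent")
    gap = group.mean(axis=(-2, -1))
    h = np.maximum(gap @ w1 + b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))


def apply_channel_attention(
    groups: Sequence[np.ndarray], maps: Sequence[np.ndarray]
) -> np.ndarray:
    """Groupwise weighted sum: C = sum_n (C^n ⊙ G^n), shape (C/N, H, W)."""
    if len(groups) != len(maps):
        raise InputError("one attention map per group is required")
    out = None
    for g, m in zip(groups, maps):
        g = np.asarray(g)
        m = np.asarray(m)
        if m.shape[0] != g.shape[0]:
            raise InputError(
                f"attention map length {m.shape[0]} does not match group channels {g.shape[0]}"
            )
        term = m[:, None, None] * g
        out = term if out is None else out + term
    return out


def spatial_descriptor(c: np.ndarray, variant: str = "concat") -> np.ndarray:
    """Channel-wise average and max maps, stacked (2, H, W) or summed (1, H, W)."""
    c = np.asarray(c)
    avg = c.mean(axis=0, keepdims=True)
    mx = c.max(axis=0, keepdims=True)
    if variant == "concat":
        return np.concatenate([avg, mx], axis=0)
    if variant == "sum":
        return avg + mx
    raise ConfigurationError(f"unknown spatial-descriptor variant {variant!r}")


def spatial_attention(
    c: np.ndarray, conv_weight: np.ndarray, variant: str = "concat"
) -> np.ndarray:
    """Per-position sigmoid gate from the pooled descriptors, applied to C."""
    c = np.asarray(c)
    if not np.all(np.isfinite(c)):
        raise InputError("spatial attention input must be finite")
    sc = spatial_descriptor(c, variant)
    logits = _conv_same(sc, conv_weight)
    gate = 1.0 / (1.0 + np.exp(-logits))
    return gate * c


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------

class ResidualAttentionModule(Module):
    """Shared 3x3 conv K applied to rotated subgroups with y0 gating.

    Operates on all N groups at once: the input is viewed as
    ``(B, N, S, cs, H, W)`` and the group axis is folded into the batch so
    the shared kernel runs once per subgroup index."""

    def __init__(self, group_channels: int, subgroups: int, rng: np.random.Generator,
                 slope: float = 0.01):
        super().__init__()
        if group_channels % subgroups:
            raise ConfigurationError(
                f"subgroups {subgroups} must divide group channels {group_channels}"
            )
        self.subgroups = subgroups
        self.sub_channels = group_channels // subgroups
        self.kernel = Conv2d(self.sub_channels, self.sub_channels, 3, rng=rng, slope=slope)

    def forward(self, x: Tensor, n_groups: int = 1) -> Tensor:
        """(B, N*S*cs, H, W) -> same shape, subgroup-rotated/gated."""
        b, c, h, w = x.shape
        cs, s_count = self.sub_channels, self.subgroups
        x6 = ag.reshape(x, (b, n_groups, s_count, cs, h, w))
        parts: List[Tensor] = []
        for s in range(s_count):
            xs = ag.reshape(ag.narrow(x6, 2, s, 1), (b * n_groups, cs, h, w))
            parts.append(self.kernel(ag.rot90(xs, s % 4)))
        y0 = parts[0]
        ys = [y0] + [ag.mul(p, y0) for p in parts[1:]]
        stacked = ag.concat(
            [ag.reshape(p, (b, n_groups, 1, cs, h, w)) for p in ys], axis=2
        )
        return ag.reshape(stacked, (b, c, h, w))


class ChannelAttentionModule(Module):
    """Shared squeeze-excitation FC pair producing per-channel gates."""

    def __init__(self, group_channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(-(-group_channels // reduction), 1)
        self.fc1 = Linear(group_channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, group_channels, rng=rng)

    def forward(self, g: Tensor) -> Tensor:
        gap = ag.mean(g, (2, 3))
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(gap))))


class SpatialAttentionModule(Module):
    def __init__(self, variant: str, rng: np.random.Generator):
        super().__init__()
        self.variant = variant
        self.conv = Conv2d(2 if variant == "concat" else 1, 1, 3, rng=rng)

    def forward(self, c: Tensor) -> Tensor:
        avg = ag.mean(c, (1,), keepdims=True)
        mx = ag.amax(c, 1, keepdims=True)
        sc = ag.concat([avg, mx], axis=1) if self.variant == "concat" else ag.add(avg, mx)
        gate = ag.sigmoid(self.conv(sc))
        return ag.mul(c, gate)


class AttentionBlock(Module):
    """Channel shuffle -> per-group residual attention -> channel attention
    (groupwise weighted sum to C/N channels) -> spatial attention -> learned
    1x1 expansion back to C channels, added residually to the block input."""

    def __init__(self, channels: int, cfg: AttentionConfig, rng: np.random.Generator,
                 slope: float = 0.01):
        super().__init__()
        n, s = cfg.groups, cfg.subgroups
        if channels % (n * s):
            raise ConfigurationError(
                f"attention N*S = {n}*{s} must divide the stage width {channels}"
            )
        self.cfg = cfg
        self.channels = channels
        self.group_channels = channels // n
        self.perm = shuffle_permutation(channels, n, s)
        self.residual = ResidualAttentionModule(self.group_channels, s, rng, slope)
        self.channel = ChannelAttentionModule(self.group_channels, cfg.reduction, rng)
        self.spatial = SpatialAttentionModule(cfg.variant, rng)
        self.restore = Conv2d(self.group_channels, channels, 1, rng=rng, slope=slope)

    def forward(self, x: Tensor) -> Tensor:
        n = self.cfg.groups
        cg = self.group_channels
        b, c, hh, ww = x.shape
        h = ag.index_channels(x, self.perm)
        g = self.residual.forward(h, n_groups=n)  # (B, C, H, W), grouped layout
        g5 = ag.reshape(g, (b, n, cg, hh, ww))
        gap = ag.mean(g5, (3, 4))  # (B, N, cg)
        wts = ag.sigmoid(self.channel.fc2(ag.relu(self.channel.fc1(gap))))
        att = ag.mul(g5, ag.reshape(wts, (b, n, cg, 1, 1)))
        attended = ag.sum_(att, axis=1)  # groupwise weighted sum -> (B, cg, H, W)
        out = self.spatial(attended)
        return ag.add(x, self.restore(out))
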