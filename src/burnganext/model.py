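"""Network construction, inference, shape audit and parameter accounting.

The backbone is a 50-layer grouped-convolution residual network: a wide 5x5
stem, four bottleneck stages (1x1 reduce -> 3x3 grouped -> 1x1 expand, with
identity or projected shortcuts), global average pooling and a softmax head.
Leaky ReLU follows every convolution; batch normalization follows every
convolution as well (needed for trainability) but is excluded from the
stage-tabulation parameter convention, which counts only the tabulated
convolution weights.
"""

from __future__ import annotations

import io
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import autograd as ag
from . import ops
from .attention import AttentionBlock
from .autograd import Tensor
from .config import ConvSpec, ModelConfig, StageSpec
from .errors import ConfigurationError, InputError, UsageError
from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    LeakyReLU,
    Linear,
    LocalResponseNorm,
    MaxPool2d,
    Module,
)

__all__ = [
    "NetworkModel",
    "build_model",
    "derive_shapes",
    "count_parameters",
    "count_parameters_breakdown",
    "save_checkpoint",
    "load_checkpoint",
]

PARAM_CONVENTIONS = ("stage_tabulation", "full_backbone", "all")


class Bottleneck(Module):
    """1x1 -> grouped 3x3 -> 1x1 with a residual shortcut.

    The shortcut is the identity when shapes agree, otherwise a 1x1
    projection (with batch norm).  Activations sit after each conv's batch
    norm; nothing follows the residual addition, so a block whose three conv
    weights are zero is exactly the identity."""

    def __init__(self, cin: int, specs: Tuple[ConvSpec, ...], stride: int,
                 slope: float, rng: np.random.Generator, stage_name: str):
        super().__init__()
        s1, s2, s3 = specs
        try:
            self.conv1 = Conv2d(cin, s1.out_channels, s1.kernel, rng=rng, slope=slope)
            self.conv2 = Conv2d(
                s1.out_channels, s2.out_channels, s2.kernel,
                stride=stride, groups=s2.groups, rng=rng, slope=slope,
            )
            self.conv3 = Conv2d(s2.out_channels, s3.out_channels, s3.kernel, rng=rng, slope=slope)
        except ValueError as exc:
            raise ConfigurationError(f"stage {stage_name}: {exc}") from exc
        self.bn1 = BatchNorm2d(s1.out_channels)
        self.bn2 = BatchNorm2d(s2.out_channels)
        self.bn3 = BatchNorm2d(s3.out_channels)
        self.act = LeakyReLU(slope)
        if cin != s3.out_channels or stride != 1:
            self.proj: Optional[Conv2d] = Conv2d(cin, s3.out_channels, 1, stride=stride,
                                                 rng=rng, slope=slope)
            self.proj_bn: Optional[BatchNorm2d] = BatchNorm2d(s3.out_channels)
        else:
            self.proj = self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.act(self.bn1(self.conv1(x)))
        y = self.act(self.bn2(self.conv2(y)))
        y = self.act(self.bn3(self.conv3(y)))
        sc = x if self.proj is None else self.proj_bn(self.proj(x))
        return ag.add(sc, y)


class _PlainConv(Module):
    def __init__(self, cin: int, spec: ConvSpec, stride: int, slope: float,
                 rng: np.random.Generator, stage_name: str):
        super().__init__()
        try:
            self.conv = Conv2d(cin, spec.out_channels, spec.kernel, stride=stride,
                               groups=spec.groups, rng=rng, slope=slope)
        except ValueError as exc:
            raise ConfigurationError(f"stage {stage_name}: {exc}") from exc
        self.bn = BatchNorm2d(spec.out_channels)
        self.act = LeakyReLU(slope)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class _Stage(Module):
    def __init__(self, blocks: List[Module], attention: Optional[AttentionBlock],
                 lrn: Optional[LocalResponseNorm]):
        super().__init__()
        self.blocks = blocks
        self.attention = attention
        self.lrn = lrn

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        if self.attention is not None:
            x = self.attention(x)
        if self.lrn is not None:
            x = self.lrn(x)
        return x


class NetworkModel(Module):
    """The built network: stem, bottleneck stages, GAP + softmax head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        slope = config.leaky_slope
        lrn_stages = set(config.lrn.stages) if config.lrn else set()
        att_stages = set(config.attention.stages) if config.attention else set()

        stem_spec = config.stages[0]
        if len(stem_spec.ops) != 1:
            raise ConfigurationError("the first stage must hold a single stem convolution")
        cin = config.input_shape[0]
        self.stem = _PlainConv(cin, stem_spec.ops[0], stem_spec.stride, slope, rng, stem_spec.name)
        self.stem_lrn = self._make_lrn() if stem_spec.name in lrn_stages else None
        self.pool = (
            MaxPool2d(stem_spec.pool.window, stem_spec.pool.stride) if stem_spec.pool else None
        )
        width = stem_spec.ops[0].out_channels

        self.stage_names: List[str] = []
        self.stages: List[_Stage] = []
        for spec in config.stages[1:]:
            blocks: List[Module] = []
            for rep in range(spec.repeats):
                stride = spec.stride if rep == 0 else 1
                if len(spec.ops) == 3:
                    blocks.append(Bottleneck(width, spec.ops, stride, slope, rng, spec.name))
                    width = spec.ops[-1].out_channels
                else:
                    for op in spec.ops:
                        blocks.append(_PlainConv(width, op, stride, slope, rng, spec.name))
                        width = op.out_channels
                        stride = 1
            attention = (
                AttentionBlock(width, config.attention, rng, slope)
                if spec.name in att_stages
                else None
            )
            lrn = self._make_lrn() if spec.name in lrn_stages else None
            self.stages.append(_Stage(blocks, attention, lrn))
            self.stage_names.append(spec.name)

        self.gap = GlobalAvgPool()
        self.head = Linear(width, config.num_classes, rng=rng)
        self.feature_width = width

    def _make_lrn(self) -> LocalResponseNorm:
        p = self.config.lrn
        return LocalResponseNorm(p.t, p.alpha, p.beta, p.n)

    # -- forward paths -----------------------------------------------------
    def forward_logits(self, x: Tensor, trace: Optional[List[Tuple[str, tuple]]] = None) -> Tensor:
        stem_name = self.config.stages[0].name
        x = self.stem(x)
        if trace is not None:
            trace.append((stem_name, x.shape[1:]))
        if self.stem_lrn is not None:
            x = self.stem_lrn(x)
        if self.pool is not None:
            x = self.pool(x)
            if trace is not None:
                trace.append(("pool", x.shape[1:]))
        for name, stage in zip(self.stage_names, self.stages):
            x = stage(x)
            if trace is not None:
                trace.append((name, x.shape[1:]))
        x = self.gap(x)
        if trace is not None:
            trace.append(("gap", x.shape[1:]))
        logits = self.head(x)
        if trace is not None:
            trace.append(("softmax", (self.config.num_classes,)))
        return logits

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        c, h, w = self.config.input_shape
        if batch.ndim != 4 or batch.shape[1:] != (c, h, w):
            raise InputError(
                f"expected a batch of shape (n, {c}, {h}, {w}), got {batch.shape}"
            )
        if not np.all(np.isfinite(batch)):
            raise InputError("batch contains non-finite values")
        return batch

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Class-probability matrix (n, k); rows sum to one."""
        logits = self.forward_logits(Tensor(self._check_batch(batch)))
        return ops.softmax(logits.data, axis=1)

    def forward_trace(self, batch: np.ndarray) -> List[Tuple[str, tuple]]:
        trace: List[Tuple[str, tuple]] = [("input", tuple(self.config.input_shape))]
        self.forward_logits(Tensor(self._check_batch(batch)), trace=trace)
        return trace

    def predict(self, batch: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class codes, evaluated in chunks."""
        outs = [
            np.argmax(self.forward(batch[i: i + batch_size]), axis=1)
            for i in range(0, len(batch), batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty(0, dtype=int)

    def predict_proba(self, batch: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            self.forward(batch[i: i + batch_size]) for i in range(0, len(batch), batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty((0, self.config.num_classes))


def build_model(config: ModelConfig, seed: int = 0) -> NetworkModel:
    """Construct the network described by ``config`` with seedable He init."""
    return NetworkModel(config, seed=seed)


# ---------------------------------------------------------------------------
# shape audit
# ---------------------------------------------------------------------------

def derive_shapes(config: ModelConfig) -> List[Tuple[str, tuple]]:
    """The (stage, C x H x W) trace under ceil-mode stride arithmetic,
    computed from the config alone (no tensors involved)."""
    config.validate()
    c, h, w = config.input_shape
    if h <= 0 or w <= 0 or c <= 0:
        raise ConfigurationError(f"non-positive input extent {config.input_shape}")
    trace: List[Tuple[str, tuple]] = [("input", (c, h, w))]

    def down(size: int, stride: int) -> int:
        out = -(-size // stride)
        if out <= 0:
            raise ConfigurationError("non-positive spatial size in shape trace")
        return out

    for i, spec in enumerate(config.stages):
        h, w = down(h, spec.stride), down(w, spec.stride)
        c = spec.ops[-1].out_channels
        trace.append((spec.name, (c, h, w)))
        if spec.pool is not None:
            h, w = down(h, spec.pool.stride), down(w, spec.pool.stride)
            trace.append(("pool", (c, h, w)))
    trace.append(("gap", (c,)))
    trace.append(("softmax", (config.num_classes,)))
    return trace


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def _tabulated_counts(config: ModelConfig) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    cin = config.input_shape[0]
    for spec in config.stages:
        total = 0
        for _ in range(spec.repeats):
            for op in spec.ops:
                total += op.weight_count(cin)
                cin = op.out_channels
        counts[spec.name] = total
    return counts


def _projection_counts(config: ModelConfig) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    cin = config.stages[0].ops[-1].out_channels
    for spec in config.stages[1:]:
        cout = spec.ops[-1].out_channels
        counts[spec.name] = cin * cout if (cin != cout or spec.stride != 1) else 0
        cin = cout
    return counts


def count_parameters_breakdown(config: ModelConfig, convention: str = "stage_tabulation") -> Dict[str, int]:
    """Per-stage trainable-weight counts under the named convention."""
    if convention not in PARAM_CONVENTIONS:
        raise UsageError(
            f"unknown counting convention {convention!r}; choose from {PARAM_CONVENTIONS}"
        )
    config.validate()
    counts = _tabulated_counts(config)
    if convention == "stage_tabulation":
        return counts
    proj = _projection_counts(config)
    for name, extra in proj.items():
        counts[name] += extra
    if convention == "full_backbone":
        return counts
    model = build_model(config, seed=0)
    total_all = sum(p.data.size for p in model.parameters())
    counts["other (bn, attention, head)"] = total_all - sum(counts.values())
    return counts


def count_parameters(config: ModelConfig, convention: str = "stage_tabulation") -> int:
    """Trainable-parameter total under an explicit counting convention.

    ``stage_tabulation``: only the tabulated stage convolutions (grouped conv
    weight = kh*kw*(Cin/groups)*Cout); ``full_backbone`` additionally counts
    the stage-boundary 1x1 projection shortcuts; ``all`` counts every
    trainable scalar in the built model (batch norm, attention, head
    included).
    """
    return sum(count_parameters_breakdown(config, convention).values())


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: NetworkModel, path) -> None:
    """Single-file weights + embedded YAML config."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    cfg = yaml.safe_dump(model.config.to_dict(), sort_keys=False)
    with open(path, "wb") as fh:
        np.savez(fh, config=np.array(cfg), seed=np.array(model.seed), **arrays)


def load_checkpoint(path) -> NetworkModel:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig.from_dict(yaml.safe_load(str(data["config"])))
        model = NetworkModel(cfg, seed=int(data["seed"]))
        for i, p in enumerate(model.parameters()):
            p.data = data[f"p{i}"].copy()
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"b{i}"]
    return model
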