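"""Declarative model topology and run configuration.

The network is specified as data: a sequence of :class:`StageSpec` entries,
each an ordered list of convolution descriptors repeated ``repeats`` times.
``burnganext50()`` builds the slimmed variant (5x5 stem of width 256,
narrower bottlenecks) and ``resnext50()`` the standard ResNeXt-50 backbone.

All spatial downsampling uses ceil-mode "same" padding; stage ``stride``
applies to the 3x3 convolution of the stage's first bottleneck.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import yaml

from .errors import ConfigurationError
from .ops import LRNParams

__all__ = [
    "ConvSpec",
    "PoolSpec",
    "StageSpec",
    "AttentionConfig",
    "ModelConfig",
    "SynthConfig",
    "TrainingHyperparams",
    "burnganext50",
    "resnext50",
    "load_model_config",
    "save_model_config",
]


@dataclasses.dataclass(frozen=True)
class ConvSpec:
    kernel: Tuple[int, int]
    out_channels: int
    groups: int = 1

    def weight_count(self, in_channels: int) -> int:
        kh, kw = self.kernel
        return kh * kw * (in_channels // self.groups) * self.out_channels


@dataclasses.dataclass(frozen=True)
class PoolSpec:
    #: overlapping pooling: stride < window (the stem pool is 3x3, stride 2)
    window: int = 3
    stride: int = 2


@dataclasses.dataclass(frozen=True)
class StageSpec:
    name: str
    ops: Tuple[ConvSpec, ...]
    repeats: int = 1
    stride: int = 1  # spatial stride of the first block (on its 3x3 conv)
    pool: Optional[PoolSpec] = None

    def validate(self, cardinality: int) -> None:
        if self.repeats < 1:
            raise ConfigurationError(f"stage {self.name}: repeats must be >= 1, got {self.repeats}")
        for op in self.ops:
            if op.out_channels <= 0:
                raise ConfigurationError(f"stage {self.name}: non-positive output channels")
            if op.groups > 1 and op.out_channels % op.groups:
                raise ConfigurationError(
                    f"stage {self.name}: groups {op.groups} does not divide "
                    f"output channels {op.out_channels}"
                )


@dataclasses.dataclass(frozen=True)
class AttentionConfig:
    """Residual + channel + spatial attention block settings.

    ``groups`` (N) feature groups, each split into ``subgroups`` (S, fixed at
    4 by the quarter-turn rotation index) for the residual attention module;
    ``reduction`` is the channel-attention bottleneck ratio; ``variant``
    selects how the two spatial descriptors combine (channel concatenation,
    or elementwise sum); ``stages`` names the stages after whose output one
    attention block is inserted.
    """

    groups: int = 4
    subgroups: int = 4
    reduction: int = 16
    variant: str = "concat"
    stages: Tuple[str, ...] = ("conv2", "conv3", "conv4", "conv5")

    def validate(self) -> None:
        if self.groups < 1 or self.subgroups < 1:
            raise ConfigurationError("attention groups and subgroups must be >= 1")
        if self.reduction < 1:
            raise ConfigurationError("attention reduction must be >= 1")
        if self.variant not in ("concat", "sum"):
            raise ConfigurationError(f"unknown spatial-descriptor variant {self.variant!r}")


@dataclasses.dataclass
class ModelConfig:
    input_shape: Tuple[int, int, int] = (3, 100, 100)  # (C, H, W)
    num_classes: int = 3
    cardinality: int = 32
    leaky_slope: float = 0.01
    stages: Tuple[StageSpec, ...] = ()
    lrn: Optional[LRNParams] = LRNParams()
    attention: Optional[AttentionConfig] = AttentionConfig()

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if self.cardinality < 1:
            raise ConfigurationError("cardinality must be a positive integer")
        if not self.stages:
            raise ConfigurationError("model has no stages")
        for st in self.stages:
            st.validate(self.cardinality)
        if self.attention is not None:
            self.attention.validate()
        if self.lrn is not None:
            self.lrn.validate()

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "input_shape": list(self.input_shape),
            "num_classes": self.num_classes,
            "cardinality": self.cardinality,
            "leaky_slope": self.leaky_slope,
            "stages": [
                {
                    "name": s.name,
                    "repeats": s.repeats,
                    "stride": s.stride,
                    "ops": [
                        {"kernel": list(o.kernel), "out_channels": o.out_channels, "groups": o.groups}
                        for o in s.ops
                    ],
                    "pool": None if s.pool is None else {"window": s.pool.window, "stride": s.pool.stride},
                }
                for s in self.stages
            ],
            "lrn": None
            if self.lrn is None
            else {
                "t": self.lrn.t,
                "alpha": self.lrn.alpha,
                "beta": self.lrn.beta,
                "n": self.lrn.n,
                "stages": list(self.lrn.stages),
            },
            "attention": None
            if self.attention is None
            else {
                "groups": self.attention.groups,
                "subgroups": self.attention.subgroups,
                "reduction": self.attention.reduction,
                "variant": self.attention.variant,
                "stages": list(self.attention.stages),
            },
        }
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        stages = tuple(
            StageSpec(
                name=s["name"],
                repeats=s.get("repeats", 1),
                stride=s.get("stride", 1),
                ops=tuple(
                    ConvSpec(tuple(o["kernel"]), o["out_channels"], o.get("groups", 1))
                    for o in s["ops"]
                ),
                pool=None if s.get("pool") is None else PoolSpec(**s["pool"]),
            )
            for s in d["stages"]
        )
        lrn = d.get("lrn")
        att = d.get("attention")
        return ModelConfig(
            input_shape=tuple(d.get("input_shape", (3, 100, 100))),
            num_classes=d.get("num_classes", 3),
            cardinality=d.get("cardinality", 32),
            leaky_slope=d.get("leaky_slope", 0.01),
            stages=stages,
            lrn=None
            if lrn is None
            else LRNParams(lrn["t"], lrn["alpha"], lrn["beta"], lrn["n"], tuple(lrn.get("stages", ()))),
            attention=None
            if att is None
            else AttentionConfig(
                att["groups"], att["subgroups"], att["reduction"],
                att.get("variant", "concat"), tuple(att.get("stages", ())),
            ),
        )


def _bottleneck_stage(
    name: str, width: int, out: int, repeats: int, cardinality: int, stride: int
) -> StageSpec:
    return StageSpec(
        name=name,
        ops=(
            ConvSpec((1, 1), width),
            ConvSpec((3, 3), width, groups=cardinality),
            ConvSpec((1, 1), out),
        ),
        repeats=repeats,
        stride=stride,
    )


def burnganext50(
    num_classes: int = 3,
    cardinality: int = 32,
    width_multiplier: float = 1.0,
    attention: Optional[AttentionConfig] = AttentionConfig(),
    lrn: Optional[LRNParams] = LRNParams(),
    leaky_slope: float = 0.01,
    input_shape: Tuple[int, int, int] = (3, 100, 100),
) -> ModelConfig:
    """The slimmed 50-layer topology: 5x5/256 stem, bottleneck widths
    (32, 64, 256, 512) expanding to (128, 256, 512, 1024), cardinality 32.

    ``width_multiplier`` scales every width (used for reduced-size training
    runs); the cardinality must then divide the scaled 3x3 widths.
    """
    def w(c: int) -> int:
        return max(int(round(c * width_multiplier)), 1)

    stages = (
        StageSpec("conv1", (ConvSpec((5, 5), w(256)),), repeats=1, stride=2, pool=PoolSpec(3, 2)),
        _bottleneck_stage("conv2", w(32), w(128), 3, cardinality, stride=1),
        _bottleneck_stage("conv3", w(64), w(256), 4, cardinality, stride=2),
        _bottleneck_stage("conv4", w(256), w(512), 6, cardinality, stride=2),
        _bottleneck_stage("conv5", w(512), w(1024), 3, cardinality, stride=2),
    )
    cfg = ModelConfig(
        input_shape=input_shape,
        num_classes=num_classes,
        cardinality=cardinality,
        leaky_slope=leaky_slope,
        stages=stages,
        lrn=lrn,
        attention=attention,
    )
    cfg.validate()
    return cfg


def resnext50(
    num_classes: int = 3,
    cardinality: int = 32,
    input_shape: Tuple[int, int, int] = (3, 100, 100),
) -> ModelConfig:
    """The original ResNeXt-50 column: 7x7/64 stem, widths (128, 256, 512,
    1024) expanding to (256, 512, 1024, 2048)."""
    stages = (
        StageSpec("conv1", (ConvSpec((7, 7), 64),), repeats=1, stride=2, pool=PoolSpec(3, 2)),
        _bottleneck_stage("conv2", 128, 256, 3, cardinality, stride=1),
        _bottleneck_stage("conv3", 256, 512, 4, cardinality, stride=2),
        _bottleneck_stage("conv4", 512, 1024, 6, cardinality, stride=2),
        _bottleneck_stage("conv5", 1024, 2048, 3, cardinality, stride=2),
    )
    cfg = ModelConfig(
        input_shape=input_shape,
        num_classes=num_classes,
        cardinality=cardinality,
        stages=stages,
        lrn=None,
        attention=None,
    )
    cfg.validate()
    return cfg


def load_model_config(path) -> ModelConfig:
    with open(path) as fh:
        return ModelConfig.from_dict(yaml.safe_load(fh))


def save_model_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# synthetic data / training configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SynthConfig:
    """Parameters of the synthetic burn-image generator.

    The generator paints an elliptical lesion over a skin-tone background;
    lesion colors follow the clinical color semantics of the three depth
    classes.  ``seed`` fixes the whole dataset bit-exactly.
    """

    n_per_class: int = 200
    height: int = 100
    width: int = 100
    seed: int = 0
    noise_sd: float = 8.0
    axis_range: Tuple[float, float] = (30.0, 40.0)
    center_jitter: float = 8.0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if self.axis_range[0] <= 0:
            raise ConfigurationError("lesion ellipse axes must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "SynthConfig":
        d = dict(d)
        if "axis_range" in d:
            d["axis_range"] = tuple(d["axis_range"])
        return SynthConfig(**d)


@dataclasses.dataclass
class TrainingHyperparams:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "adam"  # or "sgd"
    momentum: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
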