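import numpy as np
import pytest

from burnganext.config import (
    AttentionConfig,
    ConvSpec,
    ModelConfig,
    PoolSpec,
    StageSpec,
    SynthConfig,
)
from burnganext.ops import LRNParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_model_config(num_classes: int = 3, channels: int = 16, attention: bool = False,
                      lrn: bool = False, size: int = 24) -> ModelConfig:
    """A miniature two-stage network for fast training tests."""
    cfg = ModelConfig(
        input_shape=(3, size, size),
        num_classes=num_classes,
        cardinality=4,
        stages=(
            StageSpec("conv1", (ConvSpec((3, 3), channels),), repeats=1, stride=2,
                      pool=PoolSpec(3, 2)),
            StageSpec(
                "conv2",
                (ConvSpec((1, 1), 8), ConvSpec((3, 3), 8, groups=4), ConvSpec((1, 1), channels)),
                repeats=1,
                stride=1,
            ),
        ),
        lrn=LRNParams(stages=("conv1",)) if lrn else None,
        attention=AttentionConfig(groups=2, subgroups=4, reduction=4, stages=("conv2",))
        if attention
        else None,
    )
    cfg.validate()
    return cfg


@pytest.fixture
def tiny_config():
    return tiny_model_config()


@pytest.fixture(scope="session")
def small_synth_records():
    """A small deterministic synthetic dataset shared across tests."""
    from burnganext.data import generate_dataset

    cfg = SynthConfig(n_per_class=20, height=48, width=48, seed=7)
    records, manifest = generate_dataset(cfg)
    return records, manifest
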