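import numpy as np
import pytest

from macn.macn_model import ModelConfig
from macn.synthetic_data import generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small geometry for fast unit tests: 64x64 patches, narrow backbone."""
    return ModelConfig(backbone_width_multiplier=0.25, input_size=64, seed=0)


@pytest.fixture
def small_spec():
    """A 128x128 scene spec with structures scaled to fit the small canvas."""
    from dataclasses import replace

    from tests_support import small_template
    return replace(small_template(), seed=7)


@pytest.fixture
def small_scene(small_spec):
    return generate_scene(small_spec)
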