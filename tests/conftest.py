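import logging

import numpy as np
import pytest

from mothwing.pattern_metrics import build_gabor_bank
from mothwing.synthetic_wings import EffectConfig, WingSpec, generate_specimen

logging.getLogger("mothwing").setLevel(logging.ERROR)


def make_spec(seed: int = 0, **overrides) -> WingSpec:
    base = dict(
        sex="female",
        taxon="badiata",
        wear=1,
        collection_year=2000,
        latitude=60.5,
        longitude=25.0,
        collection_group="loc0_2000",
        seed=seed,
    )
    base.update(overrides)
    return WingSpec(**base)


@pytest.fixture(scope="session")
def small_bank():
    """Cheap 2-scale bank for unit tests (wavelengths 2 and 4 px)."""
    return build_gabor_bank(scales_cm=(0.0625, 0.125), px_per_cm=32.0)


@pytest.fixture(scope="session")
def sim_bank():
    """3-scale bank matching the fast simulation settings."""
    return build_gabor_bank(scales_cm=(0.0625, 0.125, 0.25), px_per_cm=32.0)


@pytest.fixture()
def sample_image():
    return generate_specimen(make_spec(seed=7), EffectConfig(), size_px=(64, 96), px_per_cm=32.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
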