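import numpy as np
import pytest

from regioncode import embed_features
from regioncode.regions import GaussianSmoother, RegionConfig
from regioncode.synthetic import SyntheticConfig, generate_stimulus_set


@pytest.fixture(scope="session")
def small_config():
    """Compact stated-world config for fast unit tests (10 x 8 stimuli)."""
    return SyntheticConfig(n_categories=10, n_per_category=8, seed=3)


@pytest.fixture(scope="session")
def full_config():
    """Full-size stated world: 50 categories x 10 exemplars."""
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def stimuli(small_config):
    return generate_stimulus_set(small_config)


@pytest.fixture(scope="session")
def space(stimuli):
    return embed_features(stimuli, method="none")


@pytest.fixture(scope="session")
def region_config():
    # sq preset for ~100-stimulus spaces, matching the 80-stimulus test world
    return RegionConfig(n_permutations=200, sq=0.11, seed=0)


@pytest.fixture(scope="session")
def smoother(space, region_config):
    return GaussianSmoother(space, region_config.kernel_sd, None,
                            region_config.resolution,
                            region_config.mask_radius_factor)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
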