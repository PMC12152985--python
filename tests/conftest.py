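import numpy as np
import pytest

from hmisaccess.config import RegionConfig
from hmisaccess.synthetic import generate_region


@pytest.fixture(scope="session")
def small_config() -> RegionConfig:
    """A 60x60-cell scenario small enough for per-test travel-time runs."""
    return RegionConfig(n_rows=60, n_cols=60, n_facilities=30, seed=11)


@pytest.fixture(scope="session")
def small_region(small_config):
    return generate_region(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
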