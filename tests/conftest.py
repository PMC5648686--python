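import numpy as np
import pytest

from renlichen.districts import load_packaged_districts
from renlichen.synthetic import SyntheticConfig, generate_district_set


@pytest.fixture(scope="session")
def packaged_districts():
    return load_packaged_districts()


@pytest.fixture(scope="session")
def synthetic_noisefree():
    """Small noise-free synthetic set for exact-recovery style tests."""
    cfg = SyntheticConfig(n_districts=8, obs_noise_sd=0.0, seed=5)
    return generate_district_set(cfg)


@pytest.fixture(scope="session")
def synthetic_noisy20():
    """A 20-district set at the standard 5% observation noise."""
    cfg = SyntheticConfig(seed=42, obs_noise_sd=0.05)
    return generate_district_set(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
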