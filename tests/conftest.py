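import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vatfood import Dataset, SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset() -> Dataset:
    """Small synthetic-Europe dataset shared across tests."""
    return generate_dataset(SyntheticConfig(seed=1, n_countries=8))


@pytest.fixture(scope="session")
def full_dataset() -> Dataset:
    """Full-size synthetic Europe (28 countries x 24 groups)."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
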