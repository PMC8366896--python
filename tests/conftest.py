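import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_samples() -> pd.DataFrame:
    """One default synthetic rumen dataset shared across tests."""
    from rumenbalance import synthetic
    return synthetic.gen_rumen_samples(seed=1234)


@pytest.fixture(scope="session")
def plants() -> pd.DataFrame:
    from rumenbalance import foodscape
    return foodscape.load_plants()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)
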