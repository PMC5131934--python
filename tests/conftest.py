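import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "sigquant",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("sigquant")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small in-memory synthetic cohort shared by module-level tests."""
    from sigquant.synth import GeneratorConfig, simulate_cohort

    cfg = GeneratorConfig(n_subjects=6, n_genuine=8, n_forgery=8, seed=424242)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort) -> pd.DataFrame:
    from sigquant import extract_features

    return extract_features(small_cohort.signatures)
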