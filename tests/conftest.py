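import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pasablood.freq_features import extract_all_features
from pasablood.prep import preprocess_replicates
from pasablood.synthetic import CohortSpec, GeneratorConfig, generate_cohort, generate_replicates

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def pa_replicates(gen_config):
    return generate_replicates(gen_config, "PA", 1)


@pytest.fixture(scope="session")
def pa_avg(pa_replicates):
    return preprocess_replicates(pa_replicates)


@pytest.fixture(scope="session")
def pa_features(pa_avg):
    return extract_all_features(pa_avg)


@pytest.fixture(scope="session")
def default_cohort():
    """The 14-subject default cohort (12 both, 1 PA-only, 1 AS-only)."""
    return generate_cohort(GeneratorConfig(seed=7), CohortSpec())


@pytest.fixture()
def rng():
    """A fresh, identically seeded generator per test (order-independent)."""
    return np.random.default_rng(20240917)
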