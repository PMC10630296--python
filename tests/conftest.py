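import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cephgrowth import (DEFAULT_TRUTH, PopulationConfig, PriorSpec,
                        generate_population)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def good_prior(truth):
    """Priors centered on the generating curve (as elicitation would give)."""
    return PriorSpec(means=truth)


@pytest.fixture(scope="session")
def pop200():
    """Default-noise population of 200 individuals."""
    return generate_population(PopulationConfig(n_individuals=200, seed=7))


@pytest.fixture(scope="session")
def pop500():
    """Default-noise population of 500 individuals, for resampling tests."""
    return generate_population(PopulationConfig(n_individuals=500, seed=19))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
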