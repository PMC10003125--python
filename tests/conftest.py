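import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ltpa_pgs import cohort_sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230426)


@pytest.fixture
def study_config():
    """The default two-population study configuration."""
    return cohort_sim.default_study_config(seed=7)


@pytest.fixture
def small_config(study_config):
    """Scaled-down cohort for fast pipeline tests."""
    import dataclasses

    return dataclasses.replace(study_config, n_per_population=(120, 110))


@pytest.fixture
def cohort(small_config):
    return cohort_sim.simulate_cohort(small_config)
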