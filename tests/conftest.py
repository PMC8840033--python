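import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leaktraj as lt

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort simulated from the study's group parameters, n = 800."""
    cfg = lt.table2_default_config(n_patients=800, seed=20)
    return lt.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_features(study_cohort):
    return lt.compute_features(study_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
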