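import numpy as np
import pytest

from lansing import CohortConfig, MortalityParams, generate_cohort
from lansing.simulate import sample_lifespan


@pytest.fixture(scope="session")
def logistic_params():
    """Well-identified logistic parameters used across recovery tests."""
    return MortalityParams("logistic", a=0.001, b=0.25, c=1.0)


@pytest.fixture(scope="session")
def logistic_lifespans(logistic_params):
    """2000 seeded lifespans from the reference logistic model."""
    rng = np.random.default_rng(2024)
    lifespans, _ = sample_lifespan(logistic_params, rng, 2000)
    return lifespans


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group synthetic cohort for I/O and pipeline smoke tests."""
    config = CohortConfig(n_per_group=(40, 40), seed=7)
    return generate_cohort(config)
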