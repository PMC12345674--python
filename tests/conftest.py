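import numpy as np
import pytest
from hypothesis import settings

from uretox.cohort import assign_strata
from uretox.simulate import SimulationConfig, default_calibration, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def study_cohort(calibration):
    """Default-size synthetic cohort (161 ASD, 71 controls), fixed seed."""
    return generate_cohort(calibration, SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def study_strata(study_cohort):
    return assign_strata(study_cohort)


@pytest.fixture(scope="session")
def big_asd_values(calibration):
    """Large single-group draw for convergence checks: normalized toxin
    values of 50,000 ASD subjects."""
    cohort = generate_cohort(
        calibration, SimulationConfig(n_asd=50_000, n_control=0, seed=11)
    )
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
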