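import numpy as np
import pytest

from sodiumsim.engine import SimulationConfig, run_scenario_pair
from sodiumsim.population import ExposureDistributionParams, generate_population


@pytest.fixture(scope="session")
def exposure_params() -> ExposureDistributionParams:
    return ExposureDistributionParams()


@pytest.fixture(scope="session")
def big_cohort(exposure_params):
    """200k-person default cohort, shared across moment and shift checks."""
    return generate_population(200_000, 2013, exposure_params, seed=1)


@pytest.fixture(scope="session")
def paired_run():
    """One calibrated 50k-person baseline/reformulation pair (seed 5)."""
    return run_scenario_pair(SimulationConfig(cohort_size=50_000, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
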