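import numpy as np
import pytest

from ctdyn.splines import NaturalCubicBasis
from ctdyn.synthetic import (SimulationParams, cohort_fixture_small,
                             simulate_joint_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    return cohort_fixture_small()


@pytest.fixture(scope="session")
def default_basis():
    return NaturalCubicBasis([180.0], (0.0, 540.0))


@pytest.fixture(scope="session")
def sim_cohort_200():
    """Medium unfloored cohort reused by LMM / joint-model tests."""
    params = SimulationParams(n_subjects=200, seed=314, floor_at_zero=False)
    return simulate_joint_cohort(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
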