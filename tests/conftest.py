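import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungkin.core import build_frame_schedule
from lungkin.kinetics import KineticParameters
from lungkin.simulate import (
    DEFAULT_SCHEDULE_SPEC,
    ArterialInputParams,
    CohortSpec,
    PhantomSpec,
    simulate_arterial_input,
    simulate_dynamic_phantom,
    simulate_lung_tac,
    simulate_test_retest_cohort,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule38():
    return build_frame_schedule(DEFAULT_SCHEDULE_SPEC)


@pytest.fixture(scope="session")
def input_fn(schedule38):
    grid = np.arange(0.0, schedule38.total_duration_s + 61.0)
    return simulate_arterial_input(ArterialInputParams(), grid)


@pytest.fixture(scope="session")
def flat_input():
    """Constant plasma/whole-blood input (equilibrium scenarios)."""
    from lungkin.input_function import InputFunction

    t = np.arange(0.0, 400.0 * 60.0 + 1.0)
    c = np.full(t.size, 10.0)
    return InputFunction(t, c, c, 1.0, ratio_source="simulated")


@pytest.fixture(scope="session")
def lung_truth():
    return KineticParameters(k1=0.03, k2=0.012, vb=0.2, delta_s=5.0)


@pytest.fixture(scope="session")
def lung_tac(lung_truth, input_fn, schedule38):
    return simulate_lung_tac(lung_truth, input_fn, schedule38)


@pytest.fixture(scope="session")
def phantom():
    """Noiseless 4-D phantom with parameter gradients (shared: expensive)."""
    return simulate_dynamic_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_test_retest_cohort(CohortSpec(param_cov=0.0, noise_scale=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_cohort():
    return simulate_test_retest_cohort(CohortSpec(param_cov=0.07, noise_scale=0.05, seed=2))
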