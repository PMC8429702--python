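import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from scnhpa import nominal_parameters, simulate
from scnhpa.schedules import constant_dark, regular_light_dark

HOURS = 24.0


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def entrained_traj(nominal):
    """Nominal individual entrained to the default 12:12 cycle, 200 days
    with a 100-day burn-in discarded."""
    return simulate(nominal, regular_light_dark(), 200 * HOURS,
                    record_from=100 * HOURS)


@pytest.fixture(scope="session")
def uncoupled_dd_traj(nominal):
    """All three couplings zeroed, constant darkness: the three compartments
    free-run at their intrinsic periods."""
    return simulate(nominal.uncoupled(), constant_dark(), 250 * HOURS,
                    record_from=170 * HOURS)


@pytest.fixture(scope="session")
def cohort64(nominal):
    """The scaled-down virtual population (64 Sobol candidates, seed 1)
    with the perturbation battery attached to accepted individuals."""
    from scnhpa.population import build_cohort, run_battery
    cohort = build_cohort(nominal, n=64, seed=1)
    run_battery(cohort, followup_days=100)
    return cohort
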