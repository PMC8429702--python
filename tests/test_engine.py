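import numpy as np
import pytest

from scnhpa import default_initial_state, run_to_limit_cycle, simulate
from scnhpa.model import state_index
from scnhpa.rhythms import find_peaks, period_stats
from scnhpa.schedules import LightSchedule, constant_dark, regular_light_dark

HOURS = 24.0


def test_determinism_bit_identical(nominal):
    a = simulate(nominal, regular_light_dark(), 20 * HOURS)
    b = simulate(nominal, regular_light_dark(), 20 * HOURS)
    assert np.array_equal(a.t, b.t)
    assert np.array_equal(a.y, b.y)


def test_grid_includes_light_switches(nominal):
    traj = simulate(nominal, regular_light_dark(), 5 * HOURS)
    for switch in (12.0, 24.0, 36.0, 48.0):
        assert np.min(np.abs(traj.t - switch)) < 1e-9
    assert np.max(np.diff(traj.t)) <= 0.05 + 1e-12


def test_vip_relaxes_to_closed_form(nominal):
    """With PER/CRY held constant, VIP follows the linear first-order
    closed form and settles at k_vs1 * PERCRY / k_dv1."""
    frozen = nominal.with_updates(k_2bm=0.0, k_2dm=0.0, k_2tm=0.0, k_3tm=0.0)
    y0 = default_initial_state()
    y0[state_index("per_cry_core")] = 2.0
    y0[state_index("vip")] = 0.0
    traj = simulate(frozen, constant_dark(), 20.0, initial=y0)
    kd = frozen["k_dv1"]
    expected = 2.0 * frozen["k_vs1"] / kd * (1.0 - np.exp(-kd * traj.t))
    np.testing.assert_allclose(traj["vip"], expected, atol=5e-7)
    assert traj["vip"][-1] == pytest.approx(2.0, abs=1e-6)


def test_period_stable_under_step_halving(nominal):
    """Halving the integration step moves the CORT period by < 0.01 h
    (the numerical gate for every downstream phase estimate)."""
    periods = []
    for h in (0.05, 0.025):
        traj = simulate(nominal, regular_light_dark(), 140 * HOURS,
                        record_from=100 * HOURS, step_h=h)
        periods.append(period_stats(traj, "cort")[0])
    assert abs(periods[0] - periods[1]) < 0.01


def test_limit_cycle_independent_of_initial_conditions(nominal):
    """Two very different starts land on the same entrained orbit."""
    alt = default_initial_state() * 3.0 + 0.5
    a = simulate(nominal, regular_light_dark(), 160 * HOURS,
                 record_from=140 * HOURS)
    b = simulate(nominal, regular_light_dark(), 160 * HOURS,
                 record_from=140 * HOURS, initial=alt)
    pa = find_peaks(*a.series("cort"))
    pb = find_peaks(*b.series("cort"))
    assert np.allclose(pa[-5:], pb[-5:], atol=0.01)


def test_run_to_limit_cycle_converges_in_darkness(nominal):
    tail, converged = run_to_limit_cycle(nominal, constant_dark())
    assert converged
    m, sd = period_stats(tail, "cort")
    assert sd < 0.01
    assert 23.5 < m < 24.2  # free-running, shorter than 24 h


def test_run_to_limit_cycle_flags_nonentrained_forcing(nominal):
    """A Zeitgeber far outside the entrainment range never settles: the
    response stays quasiperiodic and convergence is reported as data."""
    sched = LightSchedule(period=21.0, photoperiod=0.5, intensity=1.0)
    tail, converged = run_to_limit_cycle(nominal, sched, max_days=140,
                                         burn_days=40)
    assert not converged


def test_invalid_inputs(nominal):
    with pytest.raises(ValueError):
        simulate(nominal, regular_light_dark(), 0.0)
    with pytest.raises(ValueError):
        simulate(nominal, regular_light_dark(), 10.0,
                 initial=np.full(23, -1.0))


def test_trajectory_accessors(nominal):
    traj = simulate(nominal, regular_light_dark(), 3 * HOURS)
    df = traj.to_frame()
    assert df.shape[1] == 24 and df.columns[0] == "time_h"
    t, x = traj.series("cort")
    assert len(t) == len(x) == len(traj.t)
    w = traj.window(24.0, 48.0)
    assert w.t_start >= 24.0 - 1e-9 and w.t_end <= 48.0 + 1e-9
    with pytest.raises(KeyError):
        traj.series("nope")
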