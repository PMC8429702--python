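import numpy as np
import pytest

from scnhpa import simulate
from scnhpa.protocols import (alternating_shift_classify, arnold_scan,
                              compute_prc, jetlag_battery, jetlag_response,
                              transient_shift_response)
from scnhpa.rhythms import phase_shift_series
from scnhpa.schedules import regular_light_dark, PhaseShift

HOURS = 24.0


# ---------------------------------------------------------------------------
# Phase response curve
# ---------------------------------------------------------------------------

def test_prc_zero_intensity_is_flat(nominal):
    pts = compute_prc(nominal, ct_grid=[0, 6, 12, 18], pulse_intensity=0.0)
    for p in pts:
        assert p.shift_h == pytest.approx(0.0, abs=0.02)


@pytest.fixture(scope="module")
def prc24(nominal):
    return compute_prc(nominal, ct_grid=np.arange(0.0, 24.0))


def test_prc_is_type_one_continuous(prc24):
    """Type-I resetting: adjacent 1-h CT points never jump by >= 2 h."""
    shifts = np.array([p.shift_h for p in prc24])
    wrapped = np.concatenate((shifts, shifts[:1]))
    assert np.max(np.abs(np.diff(wrapped))) < 2.0


def test_prc_has_both_delay_and_advance_regions(prc24):
    """Light both delays and advances depending on circadian time, with
    contiguous regions of each sign."""
    shifts = np.array([p.shift_h for p in prc24])
    assert shifts.min() < -0.3
    assert shifts.max() > 0.3
    signs = np.sign(shifts[np.abs(shifts) > 0.1])
    flips = np.sum(np.diff(signs) != 0)
    assert flips <= 3  # coherent regions, not noise


# ---------------------------------------------------------------------------
# Arnold onions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def coarse_map(nominal):
    return arnold_scan(nominal, period_range=(21, 27), n_periods=13,
                       photoperiod_range=(0.1, 0.9), n_photoperiods=5)


def test_nominal_point_entrained(nominal):
    emap = arnold_scan(nominal, period_range=(24, 24), n_periods=1,
                       photoperiod_range=(0.5, 0.5), n_photoperiods=1)
    for v in ("vip", "avp", "cort"):
        assert emap.entrained[v][0, 0]


def test_onion_nesting(coarse_map):
    """Entrainment regions nest downstream: CORT within AVP within VIP."""
    e = coarse_map.entrained
    assert np.all(e["cort"] <= e["avp"])
    assert np.all(e["avp"] <= e["vip"])
    assert coarse_map.areas["vip"] >= coarse_map.areas["avp"] >= \
        coarse_map.areas["cort"] > 0


def test_onion_left_skew(coarse_map):
    """Light shortens the period: the constant-light free-run is faster
    than the constant-dark one."""
    assert coarse_map.tau_ll < coarse_map.tau_dd
    assert coarse_map.tau_dd == pytest.approx(23.86, abs=0.05)


# ---------------------------------------------------------------------------
# Jet lag
# ---------------------------------------------------------------------------

def test_six_hour_advance_reaches_full_shift(nominal):
    d, resync, (days, series) = jetlag_response(nominal, +6,
                                                followup_days=100)
    assert d == "advance"
    assert series[-1] == pytest.approx(6.0, abs=0.1)
    assert np.isfinite(resync)


def test_twelve_hour_inversion_adapts_by_advance(nominal):
    """With an intrinsic period below 24 h the clock prefers advancing."""
    d, resync, _ = jetlag_response(nominal, +12, followup_days=100)
    assert d == "advance"


def test_advance_then_delay_returns_to_baseline_phase(nominal):
    """+6 h at day 100, -6 h at day 170: after re-entraining twice the
    steady-state phase matches the unperturbed control."""
    sched = regular_light_dark().with_events(PhaseShift(100, 6),
                                             PhaseShift(170, -6))
    horizon = 260 * HOURS
    pert = simulate(nominal, sched, horizon, record_from=240 * HOURS)
    ctrl = simulate(nominal, regular_light_dark(), horizon,
                    record_from=240 * HOURS)
    _, s = phase_shift_series(pert, ctrl, "cort")
    assert abs(s[-1]) < 0.1


def test_battery_counts_delay_schedules(nominal):
    directions, resync, index = jetlag_battery(
        nominal, shifts=(1, 6, 12, -1, -6, -11), followup_days=80)
    assert set(directions) == {1, 6, 12, -1, -6, -11}
    assert index == sum(1 for v in directions.values() if v == "delay")
    assert directions[6] == "advance"
    assert directions[-1] == "delay"


# ---------------------------------------------------------------------------
# Shift work
# ---------------------------------------------------------------------------

def test_transient_response_zero_and_bounded(nominal):
    assert transient_shift_response(nominal, days=0) == 0.0
    m = transient_shift_response(nominal)
    assert 0.0 < m <= 12.0


def test_alternating_classification_and_onset_invariance(nominal):
    """The nominal individual's rota classification does not depend on the
    onset day; an uncoupled individual free-runs and lands in group A."""
    g1, m1, _ = alternating_shift_classify(nominal, onset_day=75)
    g2, m2, _ = alternating_shift_classify(nominal, onset_day=100)
    assert g1 == g2
    assert m1 == pytest.approx(m2, abs=0.1)
    g0, m0, _ = alternating_shift_classify(nominal.uncoupled(), weeks=12)
    assert g0 == "A"
    assert abs(m0 - 24.0) > 0.05  # free-running at its intrinsic period
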