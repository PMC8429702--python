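import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnhpa.schedules import (LightSchedule, PhaseShift, constant_dark,
                              constant_light, make_alternating, make_jetlag,
                              make_pulse, make_transient_inversion,
                              regular_light_dark)


def test_default_twelve_twelve_step():
    """ZT 0-12 lit, ZT 12-24 dark, every cycle."""
    s = regular_light_dark()
    assert s.light_at(6.0) == 1.0
    assert s.light_at(18.0) == 0.0
    assert s.light_at(0.0) == 1.0
    assert s.light_at(12.0) == 0.0
    assert s.light_at(5 * 24 + 6.0) == 1.0


def test_constant_schedules():
    dd, ll = constant_dark(), constant_light(2.0)
    for t in np.linspace(0, 200, 37):
        assert dd.light_at(t) == 0.0
        assert ll.light_at(t) == 2.0


def test_jetlag_advance_remaps_phase():
    """After a +6 h advance the schedule reads the baseline 6 h later."""
    base = regular_light_dark()
    s = make_jetlag(+6, 200)
    for t in np.linspace(200 * 24, 210 * 24, 101):
        assert s.light_at(t) == base.light_at(t + 6)
    assert s.light_at(200 * 24 + 6) == base.light_at(200 * 24 + 12)
    # before onset: untouched
    for t in np.linspace(0, 200 * 24 - 0.01, 53):
        assert s.light_at(t) == base.light_at(t)


def test_twelve_hour_shift_is_inversion():
    base = regular_light_dark()
    s = make_jetlag(+12, 75)
    for t in np.linspace(75 * 24, 90 * 24, 97):
        assert s.light_at(t) == 1.0 - base.light_at(t)


def test_zero_shift_is_identity_and_large_shift_rejected():
    base = regular_light_dark()
    s = make_jetlag(0, 10)
    for t in np.linspace(0, 40 * 24, 83):
        assert s.light_at(t) == base.light_at(t)
    with pytest.raises(ValueError):
        make_jetlag(13, 10)
    with pytest.raises(ValueError):
        make_jetlag(-12.5, 10)


@given(st.floats(0.5, 12).map(lambda h: round(h, 2)))
@settings(max_examples=20, deadline=None)
def test_advance_then_delay_restores_baseline(h):
    """+h followed by -h leaves the phase unchanged after the second event."""
    base = regular_light_dark()
    s = base.with_events(PhaseShift(100, h), PhaseShift(130, -h))
    for t in np.linspace(130 * 24, 140 * 24, 41):
        assert s.light_at(t) == base.light_at(t)


def test_transient_inversion_window():
    base = regular_light_dark()
    s = make_transient_inversion(8, 75)
    for t in np.linspace(75 * 24, 83 * 24 - 0.01, 77):
        assert s.light_at(t) == 1.0 - base.light_at(t)
    # day 9 after onset: back to baseline phase
    for t in np.linspace(84 * 24, 86 * 24, 29):
        assert s.light_at(t) == base.light_at(t)
    # symmetric photoperiod: equal lit time inside and outside the window
    grid = np.arange(75 * 24, 83 * 24, 0.1)
    ref = np.arange(60 * 24, 68 * 24, 0.1)
    lit_in = np.mean([s.light_at(t) for t in grid])
    lit_ref = np.mean([s.light_at(t) for t in ref])
    assert lit_in == pytest.approx(lit_ref, abs=0.01)  # 0.1-h sampling grid


def test_alternating_rota_repeats_weekly():
    base = regular_light_dark()
    s = make_alternating(2, 5, 75)
    for t in np.linspace(75 * 24, 82 * 24, 141):
        assert s.light_at(t) == s.light_at(t + 7 * 24)  # 168-h forcing period
    # first rota day complements the baseline
    for t in np.linspace(75 * 24, 76 * 24 - 0.01, 25):
        assert s.light_at(t) == 1.0 - base.light_at(t)
    # normal block of the week matches baseline
    for t in np.linspace(77 * 24, 82 * 24 - 0.01, 61):
        assert s.light_at(t) == base.light_at(t)


def test_pulse_on_darkness():
    s = make_pulse(120.0, 3.0, 12.0)
    grid = np.arange(0, 240, 0.05)
    vals = np.array([s.light_at(t) for t in grid])
    assert set(np.unique(vals)) == {0.0, 12.0}
    assert np.trapezoid(vals, grid) == pytest.approx(36.0, rel=1e-3)
    zero = make_pulse(120.0, 3.0, 0.0)
    assert all(zero.light_at(t) == 0.0 for t in grid[::10])
    # pulses at opposite circadian phases do not overlap
    a, b = make_pulse(100.0, 3.0, 12.0), make_pulse(112.0, 3.0, 12.0)
    on_a = {t for t in grid if a.light_at(t) > 0}
    on_b = {t for t in grid if b.light_at(t) > 0}
    assert not on_a & on_b


@given(st.floats(20, 28), st.floats(0, 1), st.integers(0, 10 ** 6))
@settings(max_examples=30, deadline=None)
def test_schedule_values_are_two_level(T, chi, it):
    """Any baseline schedule takes only the values {0, I}."""
    s = LightSchedule(period=T, photoperiod=chi, intensity=1.0)
    t = (it / 10 ** 6) * 40 * T
    assert s.light_at(t) in (0.0, 1.0)


def test_segments_agree_with_pointwise_evaluation():
    """The exported constant-light segments reproduce light_at everywhere."""
    s = make_jetlag(+6, 3, base=regular_light_dark()).with_events()
    s = s.with_events()  # no-op; keep schedule as is
    bounds, levels = s.segments(0.0, 10 * 24.0)
    assert np.all(np.diff(bounds) > 0)
    rng = np.random.default_rng(0)
    for t in rng.uniform(0, 10 * 24 - 0.01, 200):
        k = np.searchsorted(bounds, t, side="right") - 1
        assert levels[k] == s.light_at(t)


def test_photoperiod_zero_is_always_dark():
    s = LightSchedule(photoperiod=0.0)
    assert all(s.light_at(t) == 0.0 for t in np.linspace(0, 100, 53))


def test_describe_lists_events():
    s = make_jetlag(-4, 50)
    text = s.describe()
    assert "delay" in text and "4" in text and "baseline" in text
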