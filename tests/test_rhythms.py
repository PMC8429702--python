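import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnhpa.rhythms import (NoRhythmError, build_actogram, estimate_period,
                            find_peaks, peak_phase_series, period_stats,
                            resynchronization_time)
from scnhpa.synth import synth_fixture


class _Sig:
    """Minimal trajectory-like wrapper around a (t, x) pair."""

    def __init__(self, t, x):
        self._t, self._x = np.asarray(t, float), np.asarray(x, float)

    def series(self, var):
        return self._t, self._x


def test_sinusoid_peaks_recovered_to_hundredth_hour():
    t, x = synth_fixture("sinusoid", period=24, phase=6, n_days=10, dt=0.1)
    peaks = find_peaks(t, x)
    expected = 6 + 24 * np.arange(len(peaks))
    np.testing.assert_allclose(peaks, expected, atol=0.01)


def test_flat_signal_raises():
    t = np.arange(0, 240, 0.1)
    with pytest.raises(NoRhythmError):
        find_peaks(t, np.full_like(t, 3.0))


def test_close_maxima_merged_keeping_larger():
    t = np.arange(0, 240, 0.1)
    x = np.cos(2 * np.pi * t / 24) + 0.3 * np.cos(2 * np.pi * (t - 3) / 8)
    peaks = find_peaks(t, x)
    assert np.all(np.diff(peaks) >= 6.0)


@given(offset=st.floats(-5, 50), scale=st.floats(0.1, 40),
       shift=st.floats(0, 48))
@settings(max_examples=25, deadline=None)
def test_period_invariant_under_affine_and_translation(offset, scale, shift):
    """estimate_period is unchanged by y -> a*y + b and t -> t + c."""
    t, x = synth_fixture("sinusoid", period=23.3, n_days=15, dt=0.1)
    ref = estimate_period(t, x)
    assert estimate_period(t + shift, scale * x + offset) == \
        pytest.approx(ref, abs=1e-6)
    assert ref == pytest.approx(23.3, abs=0.01)


def test_period_sd_flags_unstable_series():
    t, x = synth_fixture("sinusoid", period=24, n_days=20, dt=0.1)
    m, sd = period_stats(t, x)
    assert sd < 1e-3
    with pytest.raises(NoRhythmError):
        period_stats(t[:400], x[:400])  # fewer than 8 peaks


def test_phase_shift_antisymmetric_and_exact():
    t, a = synth_fixture("sinusoid", period=24, phase=8, n_days=12, dt=0.1)
    _, b = synth_fixture("sinusoid", period=24, phase=6, n_days=12, dt=0.1)
    pa, pb = find_peaks(t, a), find_peaks(t, b)
    _, s_ab = peak_phase_series(pa, pb)   # a peaks 2 h later -> delayed
    _, s_ba = peak_phase_series(pb, pa)
    np.testing.assert_allclose(s_ab, -2.0, atol=0.01)
    np.testing.assert_allclose(s_ab, -s_ba, atol=1e-9)


def test_phase_series_unwraps_monotone_drift():
    """A free-running signal 1 h fast accumulates shift past the +/-12 h
    wrap without aliasing."""
    t, fast = synth_fixture("sinusoid", period=23, n_days=40, dt=0.1)
    _, ref = synth_fixture("sinusoid", period=24, n_days=40, dt=0.1)
    days, s = peak_phase_series(find_peaks(t, fast), find_peaks(t, ref))
    assert s[-1] > 20.0  # kept increasing beyond one half-cycle
    assert np.all(np.diff(s) > 0)


def test_resynchronization_time_and_censoring():
    days = np.arange(10)
    s = np.array([0, 1, 2, 3, 4, 5, 5.9, 6, 6, 6.0])
    assert resynchronization_time(days, s, 5.8) == 6
    capped = np.minimum(s, 5.0)
    assert resynchronization_time(days, capped, 5.8) == np.inf


def test_actogram_square_wave_half_rows():
    t, x = synth_fixture("square", period=24, phase=0, n_days=10, dt=0.05,
                         duty=0.5)
    act = build_actogram(_Sig(t, x), "x")
    frac = act.raster.mean(axis=1)
    np.testing.assert_allclose(frac, 0.5, atol=0.02)


def test_actogram_threshold_strictly_interior():
    t, x = synth_fixture("sinusoid", period=24, n_days=8, dt=0.1)
    act = build_actogram(_Sig(t, x), "x")
    frac = act.raster.mean()
    assert 0.0 < frac < 1.0
    assert act.threshold == pytest.approx(np.min(x) + 0.9 * np.ptp(x), rel=1e-6)


def test_actogram_drift_slope_matches_free_run():
    """A 23.8-h rhythm on a 24-h raster drifts ~0.2 h earlier per day."""
    t, x = synth_fixture("sinusoid", period=23.8, phase=12, n_days=25, dt=0.05)
    act = build_actogram(_Sig(t, x), "x")
    onsets = act.onset_times()
    ok = np.isfinite(onsets)
    slope = np.polyfit(np.arange(act.n_days)[ok], onsets[ok], 1)[0]
    assert slope == pytest.approx(-0.2, abs=0.03)


def test_double_plot_width():
    t, x = synth_fixture("sinusoid", period=24, n_days=8, dt=0.1)
    single = build_actogram(_Sig(t, x), "x")
    double = build_actogram(_Sig(t, x), "x", double_plot=True)
    assert double.raster.shape[1] == 2 * single.raster.shape[1]
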