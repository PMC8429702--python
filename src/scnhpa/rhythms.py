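"""Circadian descriptors of simulated (or synthetic) time series.

Phase is defined by peak times throughout ("peaking time"), not by a fitted
cosinor: peaks are discrete-grid maxima refined by a local quadratic fit,
periods are means of successive peak-to-peak intervals, and phase shifts
between two trajectories are same-day peak-time differences unwrapped
across days (advance positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal import argrelmax

__all__ = [
    "NoRhythmError", "RhythmMetrics", "Actogram",
    "find_peaks", "estimate_period", "period_stats", "rhythm_metrics",
    "peak_phase_series", "phase_shift_series", "phase_shift",
    "resynchronization_time", "build_actogram",
]

FLAT_AMPLITUDE = 1e-9
MIN_PEAK_SEPARATION_H = 6.0
HOURS_PER_DAY = 24.0


class NoRhythmError(ValueError):
    """Signal has no usable oscillation (flat, or too few peaks)."""


@dataclass(frozen=True)
class RhythmMetrics:
    """Summary rhythm descriptors for one variable of one trajectory."""

    variable: str
    peak_times: np.ndarray          # h
    period: float                   # mean peak-to-peak interval, h
    period_sd: float                # SD of the intervals, h
    amplitude: float                # max - min over the analysed window
    phase: float                    # first-peak time mod reference period, h
    reference_period: float
    entrained: bool                 # |period - ref| and SD within tolerance


@dataclass(frozen=True)
class Actogram:
    """Day-stacked binary raster of above-threshold intervals."""

    variable: str
    raster: np.ndarray              # (n_days, n_bins) booleans
    bin_h: float
    plot_period_h: float
    threshold: float
    day_offset: int                 # day index of the first row

    @property
    def n_days(self) -> int:
        return self.raster.shape[0]

    def onset_times(self) -> np.ndarray:
        """Per-day time (h into the plot period) of the first above-threshold
        bin; NaN for days without one.  Useful to quantify drift."""
        out = np.full(self.n_days, np.nan)
        for i, row in enumerate(self.raster):
            idx = np.nonzero(row)[0]
            if len(idx):
                out[i] = idx[0] * self.bin_h
        return out


def _as_series(traj_or_t, var_or_x):
    if isinstance(var_or_x, str):
        return traj_or_t.series(var_or_x)
    return (np.asarray(traj_or_t, float), np.asarray(var_or_x, float))


def find_peaks(traj_or_t, var_or_x, *, min_separation: float = MIN_PEAK_SEPARATION_H,
               rel_prominence: float = 0.25, return_heights: bool = False):
    """Peak times of a signal, refined by quadratic interpolation.

    Accepts either ``(trajectory, variable_name)`` or ``(t, x)`` arrays.
    Maxima with a prominence below ``rel_prominence`` of the signal's
    amplitude are treated as noise, and maxima closer than
    ``min_separation`` hours are merged keeping the higher one.  A flat
    signal (amplitude < 1e-9) raises :class:`NoRhythmError`.
    """
    t, x = _as_series(traj_or_t, var_or_x)
    if len(t) < 3:
        raise NoRhythmError("need at least 3 samples")
    amp = np.ptp(x)
    if amp < FLAT_AMPLITUDE:
        raise NoRhythmError("flat signal: no rhythm")

    idx, _ = signal.find_peaks(x, prominence=rel_prominence * amp)
    if len(idx) == 0:
        # fall back on plain interior maxima (e.g. very short windows)
        idx = argrelmax(x, order=1)[0]
    if len(idx) == 0:
        rising = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1
        idx = rising
    if len(idx) == 0:
        raise NoRhythmError("no interior local maxima")

    # merge close peaks, keeping the larger
    merged: list[int] = []
    for i in idx:
        if merged and t[i] - t[merged[-1]] < min_separation:
            if x[i] > x[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)

    times, heights = [], []
    for i in merged:
        if 0 < i < len(t) - 1:
            # quadratic through the three surrounding samples (grid may be
            # piecewise-uniform, so use the generic non-uniform parabola)
            t0, t1, t2 = t[i - 1], t[i], t[i + 1]
            x0, x1, x2 = x[i - 1], x[i], x[i + 1]
            d01, d12, d02 = t0 - t1, t1 - t2, t0 - t2
            denom = x0 * d12 - x1 * d02 + x2 * d01
            if abs(denom) > 1e-300:
                tp = ((x0 * (t1 + t2) * d12 - x1 * (t0 + t2) * d02
                       + x2 * (t0 + t1) * d01) / (2.0 * denom))
                if t0 <= tp <= t2:
                    la = (tp - t1) * (tp - t2) / (d01 * d02)
                    lb = (tp - t0) * (tp - t2) / (-d01 * d12)
                    lc = (tp - t0) * (tp - t1) / (d02 * d12)
                    times.append(tp)
                    heights.append(x0 * la + x1 * lb + x2 * lc)
                    continue
            times.append(t1)
            heights.append(x1)
    times_a = np.asarray(times)
    if return_heights:
        return times_a, np.asarray(heights)
    return times_a


def period_stats(traj_or_t, var_or_x, *, min_peaks: int = 8) -> tuple[float, float]:
    """(mean, SD) of successive peak-to-peak intervals.

    Requires at least ``min_peaks`` peaks; a large SD relative to the
    entrainment tolerance flags an unstable (non-locked) period.
    """
    peaks = find_peaks(traj_or_t, var_or_x)
    if len(peaks) < min_peaks:
        raise NoRhythmError(f"need >= {min_peaks} peaks, found {len(peaks)}")
    iv = np.diff(peaks)
    return float(np.mean(iv)), float(np.std(iv))


def estimate_period(traj_or_t, var_or_x, *, min_peaks: int = 8) -> float:
    """Mean peak-to-peak period in hours."""
    return period_stats(traj_or_t, var_or_x, min_peaks=min_peaks)[0]


def rhythm_metrics(traj, var: str, *, reference_period: float = 24.0,
                   entrain_tol: float = 0.05, min_peaks: int = 8) -> RhythmMetrics:
    """Full rhythm summary of one trajectory variable."""
    t, x = traj.series(var)
    peaks = find_peaks(t, x)
    if len(peaks) < min_peaks:
        raise NoRhythmError(f"need >= {min_peaks} peaks, found {len(peaks)}")
    iv = np.diff(peaks)
    period, sd = float(np.mean(iv)), float(np.std(iv))
    entrained = (abs(period - reference_period) <= entrain_tol
                 and sd <= entrain_tol)
    return RhythmMetrics(
        variable=var, peak_times=peaks, period=period, period_sd=sd,
        amplitude=float(np.ptp(x)),
        phase=float(peaks[0] % reference_period),
        reference_period=reference_period, entrained=entrained)


# ---------------------------------------------------------------------------
# Phase shifts between a perturbed and a reference trajectory
# ---------------------------------------------------------------------------

def _daily_peaks(peaks: np.ndarray) -> dict[int, float]:
    """Map day index -> peak time (the first peak of that day)."""
    out: dict[int, float] = {}
    for p in peaks:
        d = int(p // HOURS_PER_DAY)
        out.setdefault(d, p)
    return out


def _wrap_half(x: float, period: float = HOURS_PER_DAY) -> float:
    """Smallest-magnitude representative of x modulo ``period`` in (-T/2, T/2]."""
    w = (x + period / 2.0) % period - period / 2.0
    return period / 2.0 if w == -period / 2.0 else w


def peak_phase_series(perturbed_peaks: np.ndarray, reference_peaks: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Day-by-day unwrapped phase shift between two peak lists.

    The shift on day ``d`` is ``reference - perturbed`` same-day peak-time
    difference (advance positive), first reduced to its smallest-magnitude
    representative modulo 24 h and then unwrapped so that a monotone drift
    never aliases (day-to-day increments are assumed < 12 h).  Days in which
    either trajectory lacks a peak are skipped.

    Returns (day indices, shifts in hours).
    """
    per = _daily_peaks(np.asarray(perturbed_peaks, float))
    ref = _daily_peaks(np.asarray(reference_peaks, float))
    days = sorted(set(per) & set(ref))
    out_d, out_s = [], []
    prev = 0.0
    for d in days:
        raw = ref[d] - per[d]
        # choose the representative closest to the previous day's value
        k = np.round((prev - raw) / HOURS_PER_DAY)
        val = raw + k * HOURS_PER_DAY
        while val - prev > HOURS_PER_DAY / 2.0:
            val -= HOURS_PER_DAY
        while val - prev < -HOURS_PER_DAY / 2.0:
            val += HOURS_PER_DAY
        out_d.append(d)
        out_s.append(val)
        prev = val
    return np.asarray(out_d, int), np.asarray(out_s, float)


def phase_shift_series(perturbed, reference, var: str, *,
                       start_day: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped daily phase-shift series of ``var`` between two trajectories."""
    pp = find_peaks(*perturbed.series(var))
    rp = find_peaks(*reference.series(var))
    d, s = peak_phase_series(pp[pp >= start_day * HOURS_PER_DAY],
                             rp[rp >= start_day * HOURS_PER_DAY])
    return d, s


def phase_shift(perturbed, reference, var: str, day: int) -> float:
    """Signed same-day peak shift (h, advance positive) on one day.

    Antisymmetric under argument swap.  Raises :class:`NoRhythmError` if
    either trajectory lacks a peak on that day.
    """
    d, s = phase_shift_series(perturbed, reference, var)
    hit = np.nonzero(d == day)[0]
    if not len(hit):
        raise NoRhythmError(f"no matched peak pair on day {day}")
    return float(s[hit[0]])


def resynchronization_time(days: np.ndarray, shifts: np.ndarray,
                           threshold_h: float, *,
                           onset_day: int = 0) -> float:
    """First day (relative to ``onset_day``) with |shift| > threshold.

    Returns ``inf`` if the series never crosses (censored).
    """
    days = np.asarray(days)
    shifts = np.asarray(shifts)
    hit = np.nonzero(np.abs(shifts) > threshold_h)[0]
    if not len(hit):
        return float("inf")
    return float(days[hit[0]] - onset_day)


# ---------------------------------------------------------------------------
# Actograms
# ---------------------------------------------------------------------------

def build_actogram(traj, var: str, *, plot_period_h: float = 24.0,
                   double_plot: bool = False, bin_h: float = 0.1) -> Actogram:
    """Day-stacked raster of above-threshold intervals for one variable.

    The threshold is ``min + 0.9 * amplitude`` computed over the whole
    analysed window; each raster row spans ``plot_period_h`` hours (rows are
    duplicated side by side when ``double_plot``).
    """
    t, x = traj.series(var)
    if t[-1] - t[0] < 2 * plot_period_h:
        raise ValueError("need at least 2 days of signal")
    amp = np.ptp(x)
    if amp < FLAT_AMPLITUDE:
        raise NoRhythmError("flat signal: no rhythm")
    threshold = float(np.min(x) + 0.9 * amp)

    d0 = int(np.ceil(t[0] / plot_period_h - 1e-9))
    d1 = int(np.floor(t[-1] / plot_period_h + 1e-9))
    n_bins = int(round(plot_period_h / bin_h))
    rows = []
    for d in range(d0, d1):
        centers = d * plot_period_h + (np.arange(n_bins) + 0.5) * bin_h
        vals = np.interp(centers, t, x)
        rows.append(vals > threshold)
    raster = np.array(rows, dtype=bool)
    if double_plot:
        raster = np.hstack((raster[:-1], raster[1:]))
    return Actogram(variable=var, raster=raster, bin_h=bin_h,
                    plot_period_h=plot_period_h * (2 if double_plot else 1),
                    threshold=threshold, day_offset=d0)
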