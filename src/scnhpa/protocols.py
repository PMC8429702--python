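"""Named chronobiology experiments.

Each protocol is a forward simulation plus rhythm analysis:

* :func:`compute_prc` — phase response curve to a timed light pulse under
  constant darkness, with circadian time anchored at the corticosterone
  peak (CT 12).
* :func:`arnold_scan` / :func:`area_difference_curves` — entrainment
  (Arnold-onion) maps over the Zeitgeber period x photoperiod plane and
  the onion-area differences that quantify the entraining ability of one
  compartment over the next.
* :func:`jetlag_battery` — the 23 permanent phase-shift schedules
  (+1..+12 h advances, -1..-11 h delays), re-entrainment direction, the
  phase delay index and resynchronization times.
* :func:`transient_shift_response` — the 8-day light/dark inversion
  (transient shift work) and the maximal corticosterone phase excursion.
* :func:`alternating_shift_classify` — the rotating 2-day-inverted /
  5-day-normal schedule and the A/B tolerance classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import run_to_limit_cycle, simulate
from .params import ParameterSet
from .rhythms import (NoRhythmError, find_peaks, peak_phase_series,
                      period_stats, resynchronization_time)
from .schedules import (LightSchedule, Pulse, constant_dark, make_alternating,
                        make_jetlag, make_transient_inversion,
                        regular_light_dark)

__all__ = [
    "PRCPoint", "EntrainmentMap", "PerturbationReport",
    "compute_prc", "arnold_scan", "area_difference_curves",
    "jetlag_battery", "transient_shift_response", "alternating_shift_classify",
    "JETLAG_SHIFTS", "RESYNC_FRACTION",
]

HOURS_PER_DAY = 24.0

#: The jet-lag schedule battery: advances +1..+12 h, delays -1..-11 h.
JETLAG_SHIFTS: tuple[int, ...] = tuple(range(1, 13)) + tuple(range(-1, -12, -1))

#: A component counts as resynchronized once its phase shift exceeds this
#: fraction of the full adaptation path (5.8 h of a 6 h shift).
RESYNC_FRACTION = 5.8 / 6.0


@dataclass(frozen=True)
class PRCPoint:
    """Steady-state CORT phase shift (h, advance > 0) for a pulse at CT."""
    ct: float
    shift_h: float


@dataclass(frozen=True)
class EntrainmentMap:
    """Boolean entrainment raster over the (Zeitgeber period, photoperiod)
    plane, per output variable, with grid-cell area summaries."""

    periods: np.ndarray                 # Zeitgeber periods T (h)
    photoperiods: np.ndarray            # lit fractions chi
    entrained: dict[str, np.ndarray]    # var -> (nT, nchi) boolean raster
    tau_dd: float                       # free-running period in darkness
    tau_ll: float                       # free-running period in light

    @property
    def areas(self) -> dict[str, int]:
        """Entrained grid-cell counts per variable (relative areas)."""
        return {v: int(m.sum()) for v, m in self.entrained.items()}

    def area_difference(self, outer: str, inner: str) -> int:
        return self.areas[outer] - self.areas[inner]


@dataclass(frozen=True)
class PerturbationReport:
    """Per-individual tolerance metrics for the perturbation battery."""

    resync_12h_days: float              # 12-h inversion resynchronization time
    phase_delay_index: int              # of the 11 delay schedules, <= 11
    directions: dict[int, str]          # shift_h -> "advance" | "delay"
    resync_days: dict[int, float]       # shift_h -> days (inf = censored)
    transient_max_shift_h: float        # 8-day inversion, max |phase diff|
    group: str                          # "A" (fails 24 h) or "B" (holds 24 h)
    alternating_period: float
    alternating_period_sd: float


# ---------------------------------------------------------------------------
# Phase response curve
# ---------------------------------------------------------------------------

def compute_prc(params: ParameterSet, ct_grid=None, *, pulse_h: float = 3.0,
                pulse_intensity: float = 12.0, settle_cycles: int = 25,
                step_h: float = 0.05) -> list[PRCPoint]:
    """Phase response curve of corticosterone to a light pulse in darkness.

    The system is first acclimated to constant darkness; the CORT peak
    defines circadian time 12 (start of the subjective night of a nocturnal
    animal).  For each circadian time in ``ct_grid`` (default 0..23 h, in
    units where one free-running cycle spans 24 CT hours) a single pulse of
    ``pulse_h`` hours at ``pulse_intensity`` is applied and the asymptotic
    peak-time difference against the unpulsed control is reported, advances
    positive.  A zero-intensity pulse yields zero shift everywhere.
    """
    if ct_grid is None:
        ct_grid = np.arange(0.0, 24.0)
    dd = constant_dark()
    tail, converged = run_to_limit_cycle(params, dd, monitor="cort",
                                         step_h=step_h)
    if not converged:
        raise NoRhythmError("no free-running CORT rhythm in darkness")
    tau = period_stats(tail, "cort")[0]
    peaks = find_peaks(*tail.series("cort"))
    t_ref = float(peaks[-1])              # CT 12 anchor
    y0 = tail.final_state()
    t0 = tail.t_end
    horizon = t0 + (settle_cycles + 3) * tau

    ctrl = simulate(params, dd, horizon, initial=y0, t0=t0, step_h=step_h)
    ctrl_peaks = find_peaks(*ctrl.series("cort"))

    out = []
    for ct in np.asarray(ct_grid, dtype=float):
        # earliest pulse start at the requested circadian time, at least one
        # full cycle past the snapshot
        dct = (ct - 12.0) % 24.0
        t_pulse = t_ref + dct / 24.0 * tau
        while t_pulse < t0 + tau:
            t_pulse += tau
        sched = dd.with_events(Pulse(t_pulse, pulse_h, pulse_intensity))
        pert = simulate(params, sched, horizon, initial=y0, t0=t0,
                        step_h=step_h)
        pert_peaks = find_peaks(*pert.series("cort"))
        # steady-state shift: control-vs-perturbed peak difference, using
        # the nearest-peak pairing over the last few cycles
        diffs = []
        for cp in ctrl_peaks[-5:]:
            pp = pert_peaks[np.argmin(np.abs(pert_peaks - cp))]
            d = cp - pp
            d = (d + tau / 2.0) % tau - tau / 2.0
            diffs.append(d)
        out.append(PRCPoint(ct=float(ct), shift_h=float(np.mean(diffs))))
    return out


# ---------------------------------------------------------------------------
# Arnold onions
# ---------------------------------------------------------------------------

def _free_running_period(params: ParameterSet, schedule: LightSchedule,
                         var: str, step_h: float) -> float:
    tail, conv = run_to_limit_cycle(params, schedule, monitor=var,
                                    step_h=step_h, max_days=250.0)
    if not conv:
        raise NoRhythmError("free-running rhythm did not settle")
    return period_stats(tail, var)[0]


def arnold_scan(params: ParameterSet, *, period_range=(20.0, 28.0),
                photoperiod_range=(0.0, 1.0), n_periods: int = 33,
                n_photoperiods: int = 21, intensity: float = 3.0,
                entrain_tol: float = 0.05, variables=("vip", "avp", "cort"),
                burn_cycles: int = 60, analysis_cycles: int = 16,
                step_h: float = 0.05) -> EntrainmentMap:
    """Entrainment raster over the (Zeitgeber period, photoperiod) plane.

    A grid point is entrained for a variable iff, after ``burn_cycles``
    forcing cycles, the variable's mean peak-to-peak period matches the
    Zeitgeber period within ``entrain_tol`` hours with a stable (SD within
    tolerance) cycle.  The onion tips at photoperiod 0 and 1 correspond to
    the free-running periods in darkness and in light.

    The default scan Zeitgeber strength is 3 (not the baseline 1): with the
    saturating photoreceptor constant K_l = 50, intensity 1 produces an
    onion only ~1 h wide in which the three compartments are
    indistinguishable.  Intensity 3 is the strongest Zeitgeber that keeps
    the nominal (T = 24 h, photoperiod 0.5) point entrained for all three
    outputs, and it yields the characteristic nested morphology (VIP region
    widest, CORT narrowest, left-skewed with a rhythmic constant-light
    limit).
    """
    Ts = np.linspace(*period_range, n_periods)
    chis = np.linspace(*photoperiod_range, n_photoperiods)
    rasters = {v: np.zeros((len(Ts), len(chis)), dtype=bool)
               for v in variables}
    for i, T in enumerate(Ts):
        for j, chi in enumerate(chis):
            sched = LightSchedule(period=float(T), photoperiod=float(chi),
                                  intensity=intensity)
            t_end = (burn_cycles + analysis_cycles) * T
            traj = simulate(params, sched, t_end, step_h=step_h,
                            record_from=burn_cycles * T)
            for v in variables:
                try:
                    m, sd = period_stats(traj, v)
                except NoRhythmError:
                    continue
                rasters[v][i, j] = (abs(m - T) <= entrain_tol
                                    and sd <= entrain_tol)
    tau_dd = _free_running_period(params, constant_dark(), "vip", step_h)
    try:
        tau_ll = _free_running_period(
            params, LightSchedule(photoperiod=1.0, intensity=intensity),
            "vip", step_h)
    except NoRhythmError:
        tau_ll = float("nan")
    return EntrainmentMap(periods=Ts, photoperiods=chis, entrained=rasters,
                          tau_dd=tau_dd, tau_ll=tau_ll)


def area_difference_curves(params: ParameterSet, coupling: str,
                           values, **scan_kwargs) -> list[tuple[float, int]]:
    """Onion-area differences as a function of one coupling strength.

    For ``coupling='v_c2'`` the difference is area(VIP) - area(AVP) (how
    well VIP entrains the shell); for ``coupling='v_coe'`` it is
    area(AVP) - area(CORT) (how well AVP entrains the HPA axis).  A smaller
    difference means a better entraining ability; the AVP->CORT curve has
    an interior minimum (maximal entraining ability) near v_coe ~ 0.8.
    """
    if coupling == "v_c2":
        outer, inner = "vip", "avp"
    elif coupling == "v_coe":
        outer, inner = "avp", "cort"
    else:
        raise ValueError("coupling must be 'v_c2' or 'v_coe'")
    scan_kwargs.setdefault("variables", (outer, inner))
    curve = []
    for val in values:
        emap = arnold_scan(params.with_updates(**{coupling: float(val)}),
                           **scan_kwargs)
        curve.append((float(val), emap.area_difference(outer, inner)))
    return curve


# ---------------------------------------------------------------------------
# Jet lag
# ---------------------------------------------------------------------------

def _burned_state(params: ParameterSet, onset_day: float, step_h: float):
    base = regular_light_dark()
    burn = simulate(params, base, onset_day * HOURS_PER_DAY, step_h=step_h)
    return burn.final_state()


def adaptation_direction(days: np.ndarray, shifts: np.ndarray,
                         threshold_h: float) -> str:
    """'advance' or 'delay' from the sign of the unwrapped shift series at
    resynchronization (or at its end when censored)."""
    hit = np.nonzero(np.abs(shifts) > threshold_h)[0]
    val = shifts[hit[0]] if len(hit) else shifts[-1]
    return "advance" if val >= 0 else "delay"


def jetlag_response(params: ParameterSet, shift_h: float, *,
                    onset_day: float = 100.0, followup_days: float = 100.0,
                    step_h: float = 0.05, _y0=None, _ctrl=None):
    """Single jet-lag schedule: returns (direction, resync_days, series).

    The resynchronization threshold follows the published convention (5.8 h
    for the 6-h schedule) proportionally: 5.8/6 of the adaptation path
    actually taken — ``|shift|`` when the system shifts in the imposed
    direction, ``24 - |shift|`` when it adapts the other way around.
    """
    onset = onset_day * HOURS_PER_DAY
    horizon = onset + followup_days * HOURS_PER_DAY
    y0 = _burned_state(params, onset_day, step_h) if _y0 is None else _y0
    if _ctrl is None:
        _ctrl = simulate(params, regular_light_dark(), horizon,
                         initial=y0, t0=onset, step_h=step_h)
    sched = make_jetlag(shift_h, onset_day)
    pert = simulate(params, sched, horizon, initial=y0, t0=onset,
                    step_h=step_h)
    pp = find_peaks(*pert.series("cort"))
    rp = find_peaks(*_ctrl.series("cort"))
    days, series = peak_phase_series(pp, rp)
    # provisional direction from a half-path threshold, then the definitive
    # path-dependent resynchronization threshold
    direction = adaptation_direction(days, series, min(abs(shift_h),
                                                       24 - abs(shift_h)) / 2)
    same_way = (direction == "advance") == (shift_h >= 0)
    path = abs(shift_h) if same_way else 24.0 - abs(shift_h)
    thr = RESYNC_FRACTION * path
    resync = resynchronization_time(days, series, thr,
                                    onset_day=int(onset_day))
    return direction, resync, (days, series)


def jetlag_battery(params: ParameterSet, shifts=JETLAG_SHIFTS, *,
                   onset_day: float = 100.0, followup_days: float = 100.0,
                   step_h: float = 0.05):
    """All 23 jet-lag schedules for one individual.

    Returns ``(directions, resync_days, phase_delay_index)`` where the
    phase delay index counts the schedules to which CORT adapts by phase
    delay (at most 11 of the 23 can be expected for a short-period clock).
    """
    onset = onset_day * HOURS_PER_DAY
    horizon = onset + followup_days * HOURS_PER_DAY
    y0 = _burned_state(params, onset_day, step_h)
    ctrl = simulate(params, regular_light_dark(), horizon, initial=y0,
                    t0=onset, step_h=step_h)
    directions: dict[int, str] = {}
    resync: dict[int, float] = {}
    for s in shifts:
        d, r, _ = jetlag_response(params, s, onset_day=onset_day,
                                  followup_days=followup_days, step_h=step_h,
                                  _y0=y0, _ctrl=ctrl)
        directions[int(s)] = d
        resync[int(s)] = r
    index = sum(1 for d in directions.values() if d == "delay")
    return directions, resync, index


# ---------------------------------------------------------------------------
# Shift work
# ---------------------------------------------------------------------------

def transient_shift_response(params: ParameterSet, *, days: float = 8.0,
                             onset_day: float = 100.0,
                             followup_days: float = 60.0,
                             step_h: float = 0.05) -> float:
    """Maximal |CORT phase difference| (h) caused by a transient inversion.

    The perturbed run (light/dark inverted for ``days`` days) is compared
    day by day against an unperturbed control; differences are taken as the
    smallest-magnitude representative modulo 24 h, so the gauge is bounded
    by 12 h.  A zero-length inversion gives 0.
    """
    if days == 0:
        return 0.0
    onset = onset_day * HOURS_PER_DAY
    horizon = onset + (days + followup_days) * HOURS_PER_DAY
    y0 = _burned_state(params, onset_day, step_h)
    ctrl = simulate(params, regular_light_dark(), horizon, initial=y0,
                    t0=onset, step_h=step_h)
    sched = make_transient_inversion(days, onset_day)
    pert = simulate(params, sched, horizon, initial=y0, t0=onset,
                    step_h=step_h)
    pp = find_peaks(*pert.series("cort"))
    rp = find_peaks(*ctrl.series("cort"))
    # wrapped (not cumulatively unwrapped) daily differences
    from .rhythms import _daily_peaks, _wrap_half
    per, ref = _daily_peaks(pp), _daily_peaks(rp)
    diffs = [abs(_wrap_half(ref[d] - per[d]))
             for d in sorted(set(per) & set(ref))]
    return float(max(diffs)) if diffs else 0.0


def alternating_shift_classify(params: ParameterSet, *, tol: float = 0.05,
                               onset_day: float = 75.0, weeks: int = 20,
                               discard_weeks: int = 2, step_h: float = 0.05):
    """Group A/B classification under the rotating 2 d-inverted/5 d-normal
    schedule.

    Group B individuals hold a stable 24 +- ``tol`` h CORT period under the
    rotation; group A individuals break lock and free-run (period below
    24 h expected).  Returns ``(group, mean_period, period_sd)``.
    """
    sched = make_alternating(2.0, 5.0, onset_day)
    t_end = (onset_day + weeks * 7.0) * HOURS_PER_DAY
    record = (onset_day + discard_weeks * 7.0) * HOURS_PER_DAY
    traj = simulate(params, sched, t_end, step_h=step_h, record_from=record)
    try:
        m, sd = period_stats(traj, "cort")
    except NoRhythmError:
        return "A", float("nan"), float("nan")
    group = "B" if (abs(m - 24.0) <= tol and sd <= tol) else "A"
    return group, m, sd


def perturbation_report(params: ParameterSet, *, onset_day: float = 100.0,
                        followup_days: float = 100.0,
                        step_h: float = 0.05) -> PerturbationReport:
    """Full battery for one individual (Figs. of merit for tolerance maps)."""
    directions, resync, index = jetlag_battery(
        params, onset_day=onset_day, followup_days=followup_days,
        step_h=step_h)
    transient = transient_shift_response(params, onset_day=onset_day,
                                         step_h=step_h)
    group, m, sd = alternating_shift_classify(params, step_h=step_h)
    return PerturbationReport(
        resync_12h_days=resync[12], phase_delay_index=index,
        directions=directions, resync_days=resync,
        transient_max_shift_h=transient, group=group,
        alternating_period=m, alternating_period_sd=sd)
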