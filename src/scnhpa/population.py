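"""Sobol-sampled virtual populations over the three coupling axes.

A virtual individual is a triple (v_l, v_c2, v_coe): light sensitivity,
VIP coupling strength onto the shell, AVP coupling strength onto the HPA
axis.  Candidates are drawn with a low-discrepancy Sobol design, and an
individual is *accepted* into the homeostatic population iff its entrained
corticosterone profile stays pointwise within a +-20% band of the nominal
profile over a Zeitgeber-time-aligned cycle (and it is entrained at all).
Accepted individuals are then pushed through the perturbation battery and
summarized into cohort-level tolerance correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc, spearmanr

from .engine import SimulationError, simulate
from .params import COUPLING_NAMES, ParameterSet
from .protocols import PerturbationReport, perturbation_report
from .rhythms import NoRhythmError, period_stats
from .schedules import regular_light_dark

__all__ = [
    "DEFAULT_RANGES", "Individual", "Cohort",
    "sobol_sample", "nominal_cort_cycle", "accept", "build_cohort",
    "run_battery", "cohort_report",
]

#: Sampling ranges for (v_l, v_c2, v_coe), centred on the nominal values.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "v_l": (0.0, 0.5),
    "v_c2": (0.0, 2.0),
    "v_coe": (0.0, 2.0),
}

HOURS_PER_DAY = 24.0


@dataclass
class Individual:
    """One virtual individual: coupling triple, acceptance, battery report."""

    v_l: float
    v_c2: float
    v_coe: float
    accepted: bool = False
    reason: str = ""
    report: PerturbationReport | None = None

    def params(self, base: ParameterSet) -> ParameterSet:
        return base.with_updates(v_l=self.v_l, v_c2=self.v_c2,
                                 v_coe=self.v_coe)


@dataclass
class Cohort:
    """A reproducible virtual population and its summaries."""

    base_params: ParameterSet
    ranges: dict[str, tuple[float, float]]
    seed: int
    individuals: list[Individual] = field(default_factory=list)

    @property
    def accepted(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.accepted]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row = dict(v_l=ind.v_l, v_c2=ind.v_c2, v_coe=ind.v_coe,
                       accepted=ind.accepted, reason=ind.reason)
            if ind.report is not None:
                r = ind.report
                row.update(resync_12h_days=r.resync_12h_days,
                           phase_delay_index=r.phase_delay_index,
                           transient_max_shift_h=r.transient_max_shift_h,
                           group=r.group,
                           alternating_period=r.alternating_period)
            rows.append(row)
        return pd.DataFrame(rows)


def sobol_sample(n: int, ranges: dict[str, tuple[float, float]] | None = None,
                 seed: int = 0, *, scramble: bool = True) -> np.ndarray:
    """``n`` low-discrepancy triples within ``ranges`` (deterministic per
    (n, ranges, seed, scramble))."""
    if n < 8:
        raise ValueError("need n >= 8 candidates")
    ranges = DEFAULT_RANGES if ranges is None else ranges
    lo = np.array([ranges[k][0] for k in COUPLING_NAMES])
    hi = np.array([ranges[k][1] for k in COUPLING_NAMES])
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("ranges must be finite")
    eng = qmc.Sobol(d=3, scramble=scramble, seed=seed)
    u = eng.random(n)
    return qmc.scale(u, lo, hi)


def nominal_cort_cycle(base: ParameterSet, *, burn_days: float = 120.0,
                       total_days: float = 150.0, dt: float = 0.1,
                       step_h: float = 0.05) -> np.ndarray:
    """Nominal entrained CORT profile over one ZT-aligned cycle (0.1-h grid)."""
    return _entrained_cycle(base, burn_days=burn_days, total_days=total_days,
                            dt=dt, step_h=step_h)[1]


def _entrained_cycle(params: ParameterSet, *, burn_days: float = 120.0,
                     total_days: float = 150.0, dt: float = 0.1,
                     step_h: float = 0.05, entrain_tol: float = 0.05):
    """Simulate to the entrained cycle; returns (period_ok, zt_profile).

    ``zt_profile`` samples CORT on [0, 24) at ``dt`` starting at a ZT 0
    (lights-on) day boundary after the burn-in.
    """
    sched = regular_light_dark()
    traj = simulate(params, sched, total_days * HOURS_PER_DAY,
                    record_from=burn_days * HOURS_PER_DAY, step_h=step_h)
    t, x = traj.series("cort")
    try:
        m, sd = period_stats(t, x)
        period_ok = abs(m - 24.0) <= entrain_tol and sd <= entrain_tol
    except NoRhythmError:
        return False, None
    day0 = np.ceil(t[0] / HOURS_PER_DAY) * HOURS_PER_DAY
    zt = day0 + np.arange(0.0, 24.0, dt)
    return period_ok, np.interp(zt, t, x)


def accept(candidate: ParameterSet, nominal_cycle: np.ndarray, *,
           band: float = 0.20, entrain_tol: float = 0.05,
           step_h: float = 0.05) -> tuple[bool, str]:
    """Homeostatic-band acceptance of one candidate parameter set.

    Accepted iff the candidate entrains (CORT period 24 +- ``entrain_tol``
    h, stable) and its ZT-aligned CORT cycle deviates pointwise from the
    nominal cycle by no more than ``band`` times the nominal cycle's
    amplitude (max - min).  The amplitude scaling keeps the criterion
    meaningful near the CORT trough, where the profile approaches zero and
    a relative band would only ever accept exact clones of the nominal
    individual.  Returns ``(flag, reason)`` with reason one of
    ``ok | not_entrained | band | simulation_failure``.
    """
    try:
        ok, cycle = _entrained_cycle(candidate, step_h=step_h,
                                     entrain_tol=entrain_tol)
    except SimulationError:
        return False, "simulation_failure"
    if not ok or cycle is None:
        return False, "not_entrained"
    tol = band * float(np.ptp(nominal_cycle))
    if np.max(np.abs(cycle - nominal_cycle)) <= tol:
        return True, "ok"
    return False, "band"


def build_cohort(base: ParameterSet, n: int = 256, *,
                 ranges: dict[str, tuple[float, float]] | None = None,
                 seed: int = 0, band: float = 0.20, step_h: float = 0.05,
                 scramble: bool = True) -> Cohort:
    """Sample ``n`` candidates and apply the CORT-band acceptance test."""
    ranges = DEFAULT_RANGES if ranges is None else ranges
    nominal = nominal_cort_cycle(base, step_h=step_h)
    cohort = Cohort(base_params=base, ranges=ranges, seed=seed)
    for v_l, v_c2, v_coe in sobol_sample(n, ranges, seed, scramble=scramble):
        ind = Individual(float(v_l), float(v_c2), float(v_coe))
        flag, reason = accept(ind.params(base), nominal, band=band,
                              step_h=step_h)
        ind.accepted, ind.reason = flag, reason
        cohort.individuals.append(ind)
    return cohort


def run_battery(cohort: Cohort, *, step_h: float = 0.05,
                onset_day: float = 100.0,
                followup_days: float = 100.0) -> Cohort:
    """Attach the perturbation battery to every accepted individual."""
    for ind in cohort.accepted:
        ind.report = perturbation_report(
            ind.params(cohort.base_params), onset_day=onset_day,
            followup_days=followup_days, step_h=step_h)
    return cohort


def cohort_report(cohort: Cohort) -> dict:
    """Cohort-level tolerance summary.

    Includes the max/min spread of 12-h resynchronization times, the group
    A/B split, and Spearman rank correlations among the tolerance metrics
    (12-h resynchronization time, phase delay index, transient-shift
    maximal excursion, group membership).  Degenerate (constant) columns
    yield NaN correlations.
    """
    rows = [ind for ind in cohort.accepted if ind.report is not None]
    out: dict = {"n_candidates": len(cohort.individuals),
                 "n_accepted": len(cohort.accepted),
                 "n_battery": len(rows)}
    if cohort.accepted:
        out["min_accepted"] = {k: min(getattr(i, k) for i in cohort.accepted)
                               for k in COUPLING_NAMES}
        out["max_accepted"] = {k: max(getattr(i, k) for i in cohort.accepted)
                               for k in COUPLING_NAMES}
    if not rows:
        return out
    resync = np.array([i.report.resync_12h_days for i in rows])
    finite = resync[np.isfinite(resync)]
    out["resync_12h_days"] = resync.tolist()
    out["resync_spread_ratio"] = (float(finite.max() / finite.min())
                                  if len(finite) and finite.min() > 0
                                  else float("nan"))
    out["phase_delay_index_max"] = max(i.report.phase_delay_index
                                       for i in rows)
    out["groups"] = {g: sum(1 for i in rows if i.report.group == g)
                     for g in ("A", "B")}

    metrics = pd.DataFrame({
        "resync_12h": resync,
        "delay_index": [i.report.phase_delay_index for i in rows],
        "transient_shift": [i.report.transient_max_shift_h for i in rows],
        "group_b": [1 if i.report.group == "B" else 0 for i in rows],
    })
    corr = {}
    cols = list(metrics)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            x, y = metrics[cols[a]], metrics[cols[b]]
            m = np.isfinite(x) & np.isfinite(y)
            if m.sum() >= 3 and x[m].nunique() > 1 and y[m].nunique() > 1:
                rho = float(spearmanr(x[m], y[m]).statistic)
            else:
                rho = float("nan")
            corr[f"{cols[a]}~{cols[b]}"] = rho
    out["spearman"] = corr
    return out
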