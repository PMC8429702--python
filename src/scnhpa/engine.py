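"""Numerical integration of the model under a light schedule.

``simulate`` produces a :class:`Trajectory` on a piecewise-uniform grid
(default spacing 0.05 h) whose nodes include every light switch, so the
step Zeitgeber is never smoothed across a discontinuity.
``run_to_limit_cycle`` discards the transient and returns a settled tail,
flagging non-convergence (used to mark non-entrained points in Arnold
scans) as data rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _integrator
from .model import STATE_NAMES, default_initial_state, state_index
from .params import ParameterSet
from .schedules import LightSchedule

__all__ = ["Trajectory", "SimulationError", "simulate", "run_to_limit_cycle"]

DEFAULT_STEP_H = 0.05


class SimulationError(RuntimeError):
    """Integration failure; carries the time at which the state degenerated."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus the 23-column state matrix and its provenance."""

    t: np.ndarray
    y: np.ndarray
    params: ParameterSet
    schedule: LightSchedule
    meta: dict[str, Any] = field(default_factory=dict)

    def series(self, var: str) -> tuple[np.ndarray, np.ndarray]:
        """(time, values) for one state variable, clipped to >= 0."""
        return self.t, np.maximum(self.y[:, state_index(var)], 0.0)

    def __getitem__(self, var: str) -> np.ndarray:
        return np.maximum(self.y[:, state_index(var)], 0.0)

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def final_state(self) -> np.ndarray:
        return np.maximum(self.y[-1], 0.0)

    def window(self, t0: float, t1: float | None = None) -> "Trajectory":
        """Restrict to grid times in [t0, t1]."""
        t1 = self.t_end if t1 is None else t1
        m = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        if not m.any():
            raise ValueError(f"empty window [{t0}, {t1}]")
        return Trajectory(self.t[m], self.y[m], self.params, self.schedule,
                          dict(self.meta))

    def to_frame(self):
        """Trajectory as a pandas DataFrame (time_h + one column per state)."""
        import pandas as pd
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.t)
        return df


def simulate(params: ParameterSet, schedule: LightSchedule, t_end: float, *,
             initial: np.ndarray | None = None, t0: float = 0.0,
             step_h: float = DEFAULT_STEP_H,
             record_from: float | None = None) -> Trajectory:
    """Integrate the model from ``t0`` to ``t_end`` hours.

    ``record_from`` trims the returned grid (the burn-in is still
    integrated).  Deterministic: identical inputs give bit-identical
    trajectories on the same platform.
    """
    if not t_end > t0:
        raise ValueError("t_end must exceed t0")
    y0 = default_initial_state() if initial is None else \
        np.asarray(initial, dtype=np.float64).copy()
    if y0.shape != (len(STATE_NAMES),):
        raise ValueError("initial state must have 23 entries")
    if np.any(~np.isfinite(y0)) or np.any(y0 < 0):
        raise ValueError("initial state must be finite and >= 0")

    bounds, levels = schedule.segments(t0, t_end)
    ts, ys, ok = _integrator.integrate_segments(y0, bounds, levels,
                                                params.to_array(), step_h)
    if not ok:
        bad = np.nonzero(~np.isfinite(ys).all(axis=1))[0]
        t_fail = float(ts[bad[0]]) if len(bad) and np.isfinite(ts[bad[0]]) else None
        raise SimulationError(
            f"state became non-finite near t = {t_fail} h", t_fail)

    traj = Trajectory(ts, ys, params, schedule,
                      meta={"step_h": step_h, "t0": t0, "n_segments": len(levels)})
    if record_from is not None and record_from > t0:
        traj = traj.window(record_from)
    return traj


def run_to_limit_cycle(params: ParameterSet, schedule: LightSchedule, *,
                       monitor: str = "cort", max_days: float = 400.0,
                       settle_tol: float = 1e-3, settle_rtol: float = 1e-4,
                       burn_days: float = 60.0, chunk_days: float = 24.0,
                       n_cycles: int = 10, cycle_hint: float = 24.0,
                       step_h: float = DEFAULT_STEP_H, t0: float = 0.0,
                       initial: np.ndarray | None = None,
                       ) -> tuple[Trajectory, bool]:
    """Integrate until the monitored variable settles onto a periodic orbit.

    Convergence requires at least ``n_cycles`` full cycles whose successive
    peak-to-peak intervals agree within ``settle_tol`` hours and whose peak
    heights agree within ``settle_rtol`` relative.  Returns the settled
    tail (>= ``n_cycles`` cycles) and a convergence flag; exhausting
    ``max_days`` returns ``converged=False`` with the final tail.
    """
    from .rhythms import NoRhythmError, find_peaks

    keep_h = (n_cycles + 2) * max(cycle_hint, 24.0)
    state = default_initial_state() if initial is None else \
        np.asarray(initial, dtype=np.float64).copy()
    t = t0
    tail: Trajectory | None = None

    # burn-in without retaining output
    burn_end = t0 + burn_days * 24.0
    traj = simulate(params, schedule, burn_end, initial=state, t0=t,
                    step_h=step_h)
    state, t = traj.final_state(), burn_end
    t_max = t0 + max_days * 24.0

    while t < t_max - 1e-9:
        t_next = min(t + chunk_days * 24.0, t_max)
        chunk = simulate(params, schedule, t_next, initial=state, t0=t,
                         step_h=step_h)
        state, t = chunk.final_state(), t_next
        if tail is None:
            tail = chunk
        else:
            tail = Trajectory(np.concatenate((tail.t[:-1], chunk.t)),
                              np.vstack((tail.y[:-1], chunk.y)),
                              params, schedule, dict(chunk.meta))
        if tail.t_end - tail.t_start > keep_h:
            tail = tail.window(tail.t_end - keep_h)
        try:
            peaks, heights = find_peaks(*tail.series(monitor),
                                        return_heights=True)
        except NoRhythmError:
            continue
        if len(peaks) < n_cycles + 1:
            continue
        intervals = np.diff(peaks[-(n_cycles + 1):])
        hs = heights[-(n_cycles + 1):]
        if (np.max(np.abs(np.diff(intervals))) < settle_tol
                and np.max(np.abs(np.diff(hs))) < settle_rtol * np.max(hs)):
            return tail, True
    return tail, False
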