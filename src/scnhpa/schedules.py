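"""Light schedules: the baseline step Zeitgeber and every perturbation protocol.

The baseline Zeitgeber is a step function with period ``T`` (h), photoperiod
``chi`` (lit fraction of the cycle) and intensity ``I``: light is on during
``[k*T, k*T + chi*T)`` for every cycle ``k``.  ZT 0 is lights-on.  Events
layered on top of the baseline remap its phase (jet-lag shifts), invert
lit and dark windows for bounded blocks (transient/rotating shift work),
switch to constant conditions, or add light pulses.

All schedules are deterministic, piecewise-constant functions of time; the
exact switch times are exported so the integrator can restart at each
discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "LightSchedule", "PhaseShift", "TransientInversion", "AlternatingShift",
    "Pulse", "ConstantAfter",
    "regular_light_dark", "constant_dark", "constant_light",
    "make_jetlag", "make_transient_inversion", "make_alternating", "make_pulse",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class PhaseShift:
    """Permanent phase remap at ``onset_day``: for t past the onset the
    schedule reads the baseline at ``t + shift_h`` (advance positive)."""
    onset_day: float
    shift_h: float

    @property
    def onset_h(self) -> float:
        return self.onset_day * HOURS_PER_DAY


@dataclass(frozen=True)
class TransientInversion:
    """Lit and dark windows swapped on ``[onset, onset + days*24)``."""
    onset_day: float
    days: float

    @property
    def onset_h(self) -> float:
        return self.onset_day * HOURS_PER_DAY

    @property
    def end_h(self) -> float:
        return (self.onset_day + self.days) * HOURS_PER_DAY


@dataclass(frozen=True)
class AlternatingShift:
    """Rotating shift work: from onset, repeating blocks of
    ``inverted_days`` inverted light followed by ``normal_days`` normal."""
    onset_day: float
    inverted_days: float = 2.0
    normal_days: float = 5.0

    @property
    def onset_h(self) -> float:
        return self.onset_day * HOURS_PER_DAY

    @property
    def block_h(self) -> float:
        return (self.inverted_days + self.normal_days) * HOURS_PER_DAY


@dataclass(frozen=True)
class Pulse:
    """Additive light pulse on ``[start_h, start_h + duration_h)``."""
    start_h: float
    duration_h: float
    intensity: float


@dataclass(frozen=True)
class ConstantAfter:
    """Constant light level (0 = darkness) from ``onset_day`` onward."""
    onset_day: float
    level: float

    @property
    def onset_h(self) -> float:
        return self.onset_day * HOURS_PER_DAY


Event = PhaseShift | TransientInversion | AlternatingShift | Pulse | ConstantAfter


@dataclass(frozen=True)
class LightSchedule:
    """Piecewise-constant light forcing.

    Parameters
    ----------
    period : Zeitgeber period T in hours.
    photoperiod : lit fraction chi of each cycle, in [0, 1].
    intensity : baseline light intensity I (dimensionless, >= 0).
    events : ordered perturbation events layered on the baseline.
    """

    period: float = 24.0
    photoperiod: float = 0.5
    intensity: float = 1.0
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        if not (self.period > 0):
            raise ValueError("Zeitgeber period must be > 0")
        if not (0.0 <= self.photoperiod <= 1.0):
            raise ValueError("photoperiod must lie in [0, 1]")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        for ev in self.events:
            if isinstance(ev, Pulse) and (ev.duration_h < 0 or ev.intensity < 0):
                raise ValueError("pulse duration and intensity must be >= 0")
            if isinstance(ev, ConstantAfter) and ev.level < 0:
                raise ValueError("constant light level must be >= 0")

    def with_events(self, *events: Event) -> "LightSchedule":
        return LightSchedule(self.period, self.photoperiod, self.intensity,
                             self.events + tuple(events))

    # ------------------------------------------------------------------
    def _phase_offset(self, t: float) -> float:
        off = 0.0
        for ev in self.events:
            if isinstance(ev, PhaseShift) and t >= ev.onset_h:
                off += ev.shift_h
        return off

    def _inverted(self, t: float) -> bool:
        inv = False
        for ev in self.events:
            if isinstance(ev, TransientInversion):
                if ev.onset_h <= t < ev.end_h:
                    inv = not inv
            elif isinstance(ev, AlternatingShift):
                if t >= ev.onset_h:
                    u = (t - ev.onset_h) % ev.block_h
                    if u < ev.inverted_days * HOURS_PER_DAY:
                        inv = not inv
        return inv

    def _constant_level(self, t: float) -> float | None:
        level = None
        for ev in self.events:
            if isinstance(ev, ConstantAfter) and t >= ev.onset_h:
                level = ev.level
        return level

    def light_at(self, t: float) -> float:
        """Light level at time ``t`` (hours, >= 0)."""
        if t < 0 or not np.isfinite(t):
            raise ValueError("time must be finite and >= 0")
        const = self._constant_level(t)
        if const is not None:
            base = const
        else:
            u = (t + self._phase_offset(t)) % self.period
            lit = u < self.photoperiod * self.period
            if self._inverted(t):
                lit = not lit
            base = self.intensity if lit else 0.0
        for ev in self.events:
            if isinstance(ev, Pulse) and ev.start_h <= t < ev.start_h + ev.duration_h:
                base += ev.intensity
        return base

    # ------------------------------------------------------------------
    def _baseline_switch_times(self, t0: float, t1: float,
                               offset: float) -> Iterable[float]:
        chi, T = self.photoperiod, self.period
        if chi <= 0.0 or chi >= 1.0:
            marks = (0.0,)
        else:
            marks = (0.0, chi * T)
        k0 = int(np.floor((t0 + offset) / T)) - 1
        k1 = int(np.ceil((t1 + offset) / T)) + 1
        for k in range(k0, k1 + 1):
            for m in marks:
                s = k * T + m - offset
                if t0 < s < t1:
                    yield s

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """All switch times of the schedule in the open interval (t0, t1)."""
        pts: set[float] = set()
        regime_edges = [t0, t1]
        for ev in self.events:
            if isinstance(ev, PhaseShift):
                regime_edges.append(ev.onset_h)
                pts.add(ev.onset_h)
            elif isinstance(ev, TransientInversion):
                pts.update((ev.onset_h, ev.end_h))
            elif isinstance(ev, AlternatingShift):
                if ev.onset_h < t1:
                    n_blocks = int(np.ceil((t1 - ev.onset_h) / ev.block_h)) + 1
                    for b in range(n_blocks):
                        start = ev.onset_h + b * ev.block_h
                        pts.add(start)
                        pts.add(start + ev.inverted_days * HOURS_PER_DAY)
            elif isinstance(ev, Pulse):
                pts.update((ev.start_h, ev.start_h + ev.duration_h))
            elif isinstance(ev, ConstantAfter):
                pts.add(ev.onset_h)
        edges = sorted(e for e in set(regime_edges) if t0 <= e <= t1)
        for a, b in zip(edges[:-1], edges[1:]):
            off = self._phase_offset(0.5 * (a + b))
            pts.update(self._baseline_switch_times(a, b, off))
        return np.array(sorted(p for p in pts if t0 < p < t1))

    def segments(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Constant-light segments covering [t0, t1].

        Returns ``(bounds, levels)`` with ``bounds`` of length m+1 and
        ``levels[i]`` the light level on ``[bounds[i], bounds[i+1])``.
        """
        if not t1 > t0:
            raise ValueError("need t1 > t0")
        inner = self.breakpoints(t0, t1)
        bounds = np.concatenate(([t0], inner, [t1]))
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        levels = np.array([self.light_at(m) for m in mids])
        return bounds, levels

    def describe(self) -> str:
        """Human-readable piecewise definition, for audit."""
        lines = [f"baseline: period {self.period} h, photoperiod "
                 f"{self.photoperiod}, intensity {self.intensity} "
                 f"(lit on [kT, kT + {self.photoperiod * self.period:g} h))"]
        for ev in self.events:
            if isinstance(ev, PhaseShift):
                kind = "advance" if ev.shift_h >= 0 else "delay"
                lines.append(f"day {ev.onset_day:g}: permanent phase "
                             f"{kind} of {abs(ev.shift_h):g} h")
            elif isinstance(ev, TransientInversion):
                lines.append(f"day {ev.onset_day:g}: light/dark inverted "
                             f"for {ev.days:g} days")
            elif isinstance(ev, AlternatingShift):
                lines.append(f"day {ev.onset_day:g}: rotating schedule, "
                             f"{ev.inverted_days:g} d inverted / "
                             f"{ev.normal_days:g} d normal, repeating")
            elif isinstance(ev, Pulse):
                lines.append(f"t = {ev.start_h:g} h: light pulse, "
                             f"{ev.duration_h:g} h at intensity {ev.intensity:g}")
            elif isinstance(ev, ConstantAfter):
                what = "constant darkness" if ev.level == 0 else \
                    f"constant light at {ev.level:g}"
                lines.append(f"day {ev.onset_day:g}: {what}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Protocol factories
# ---------------------------------------------------------------------------

def regular_light_dark(period: float = 24.0, photoperiod: float = 0.5,
                       intensity: float = 1.0) -> LightSchedule:
    """The baseline step Zeitgeber (default 12:12 light/dark)."""
    return LightSchedule(period, photoperiod, intensity)


def constant_dark() -> LightSchedule:
    """DD: free-running conditions."""
    return LightSchedule(photoperiod=0.0, intensity=0.0)


def constant_light(intensity: float = 1.0) -> LightSchedule:
    """LL at the given intensity."""
    return LightSchedule(photoperiod=1.0, intensity=intensity)


def make_jetlag(shift_h: float, onset_day: float,
                base: LightSchedule | None = None) -> LightSchedule:
    """Permanent phase shift of the light schedule at ``onset_day``.

    Positive ``shift_h`` is a phase advance (eastward travel), negative a
    delay.  Shifts beyond +/-12 h are rejected rather than silently folded.
    """
    if abs(shift_h) > 12.0:
        raise ValueError("|shift_h| must be <= 12 h")
    base = regular_light_dark() if base is None else base
    return base.with_events(PhaseShift(onset_day, shift_h))


def make_transient_inversion(days: float = 8.0, onset_day: float = 75.0,
                             base: LightSchedule | None = None) -> LightSchedule:
    """Transient shift work: light/dark inverted for ``days`` days."""
    base = regular_light_dark() if base is None else base
    return base.with_events(TransientInversion(onset_day, days))


def make_alternating(inv_days: float = 2.0, normal_days: float = 5.0,
                     onset_day: float = 75.0,
                     base: LightSchedule | None = None) -> LightSchedule:
    """Rotating shift work: ``inv_days`` inverted then ``normal_days``
    normal, repeating from ``onset_day`` (default 2 d / 5 d weekly rota)."""
    base = regular_light_dark() if base is None else base
    return base.with_events(AlternatingShift(onset_day, inv_days, normal_days))


def make_pulse(start_h: float, duration_h: float = 3.0,
               pulse_intensity: float = 12.0,
               base: LightSchedule | None = None) -> LightSchedule:
    """A light pulse on a constant-dark background (phase-response probing)."""
    base = constant_dark() if base is None else base
    return base.with_events(Pulse(start_h, duration_h, pulse_intensity))
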