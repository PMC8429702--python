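"""Run configuration: a flat YAML file driving simulations and protocols.

Schema (all sections optional)::

    seed: 0
    params:                 # overrides on the nominal parameter set
      v_l: 0.3
    schedule:
      period: 24.0
      photoperiod: 0.5
      intensity: 1.0
      events:               # ordered; one mapping per event
        - {kind: phase_shift, onset_day: 200, shift_h: 6}
        - {kind: transient_inversion, onset_day: 75, days: 8}
        - {kind: alternating, onset_day: 75, inverted_days: 2, normal_days: 5}
        - {kind: pulse, start_h: 120, duration_h: 3, intensity: 12}
        - {kind: constant, onset_day: 50, level: 0}
    solver:
      step_h: 0.05
      t_end_days: 200
      burn_days: 100
    protocol: simulate      # simulate | prc | arnold | jetlag | shiftwork | population
    protocol_options: {}    # forwarded to the protocol function
    outdir: runs/out

Unknown keys are rejected with the list of valid keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ParameterSet, nominal_parameters
from .schedules import (AlternatingShift, ConstantAfter, LightSchedule,
                        PhaseShift, Pulse, TransientInversion)

__all__ = ["RunConfig", "load_config", "schedule_from_dict"]

_TOP_KEYS = {"seed", "params", "schedule", "solver", "protocol",
             "protocol_options", "outdir"}
_SOLVER_KEYS = {"step_h", "t_end_days", "burn_days"}
_SCHEDULE_KEYS = {"period", "photoperiod", "intensity", "events"}

_EVENT_BUILDERS = {
    "phase_shift": (PhaseShift, {"onset_day", "shift_h"}),
    "transient_inversion": (TransientInversion, {"onset_day", "days"}),
    "alternating": (AlternatingShift,
                    {"onset_day", "inverted_days", "normal_days"}),
    "pulse": (Pulse, {"start_h", "duration_h", "intensity"}),
    "constant": (ConstantAfter, {"onset_day", "level"}),
}


class ConfigError(ValueError):
    """Invalid run configuration."""


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"valid keys: {sorted(allowed)}")


def schedule_from_dict(data: dict) -> LightSchedule:
    _check_keys(data, _SCHEDULE_KEYS, "schedule")
    events = []
    for ev in data.get("events", []) or []:
        ev = dict(ev)
        kind = ev.pop("kind", None)
        if kind not in _EVENT_BUILDERS:
            raise ConfigError(f"unknown event kind {kind!r}; valid kinds: "
                              f"{sorted(_EVENT_BUILDERS)}")
        cls, keys = _EVENT_BUILDERS[kind]
        _check_keys(ev, keys, f"event {kind}")
        events.append(cls(**ev))
    return LightSchedule(period=float(data.get("period", 24.0)),
                         photoperiod=float(data.get("photoperiod", 0.5)),
                         intensity=float(data.get("intensity", 1.0)),
                         events=tuple(events))


@dataclass(frozen=True)
class RunConfig:
    """Fully specified, serializable run description."""

    seed: int = 0
    params: ParameterSet = field(default_factory=nominal_parameters)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    step_h: float = 0.05
    t_end_days: float = 200.0
    burn_days: float = 100.0
    protocol: str = "simulate"
    protocol_options: dict = field(default_factory=dict)
    outdir: str = "runs/out"
    raw: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        """The archived, rerunnable description of this run."""
        return {
            "seed": self.seed,
            "params": self.params.to_dict(),
            "schedule": {
                "period": self.schedule.period,
                "photoperiod": self.schedule.photoperiod,
                "intensity": self.schedule.intensity,
                "events": [repr(e) for e in self.schedule.events],
            },
            "solver": {"step_h": self.step_h, "t_end_days": self.t_end_days,
                       "burn_days": self.burn_days},
            "protocol": self.protocol,
            "protocol_options": self.protocol_options,
        }


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> RunConfig:
    """Parse and validate a YAML config file (or an equivalent mapping)."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(data, _TOP_KEYS, "config")
    params = ParameterSet.from_dict(data.get("params", {}) or {})
    schedule = schedule_from_dict(data.get("schedule", {}) or {})
    solver = data.get("solver", {}) or {}
    _check_keys(solver, _SOLVER_KEYS, "solver")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        params=params,
        schedule=schedule,
        step_h=float(solver.get("step_h", 0.05)),
        t_end_days=float(solver.get("t_end_days", 200.0)),
        burn_days=float(solver.get("burn_days", 100.0)),
        protocol=str(data.get("protocol", "simulate")),
        protocol_options=dict(data.get("protocol_options", {}) or {}),
        outdir=str(data.get("outdir", "runs/out")),
        raw=data,
    )
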