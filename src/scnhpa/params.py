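"""Model parameters for the coupled SCN-core / SCN-shell / HPA-axis clock.

All rate constants, Michaelis constants and Hill coefficients of the
published model are carried by :class:`ParameterSet`, keyed by the symbols
used in the source model (subscripts flattened with underscores, case
preserved).  Three of them play a special role as the *coupling* axes that
define a virtual individual:

``v_l``
    light sensitivity of the photoreceptive SCN core,
``v_c2``
    strength of the VIP coupling from the core onto the shell,
``v_coe``
    strength of the AVP coupling from the shell onto the HPA axis.

Setting all three to zero decouples the three compartments, which then
free-run at their intrinsic periods (about 23.8 h core, 21.2 h shell and
24.2 h HPA axis at nominal values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "CompartmentMask",
    "nominal_parameters",
    "PARAM_NAMES",
    "COUPLING_NAMES",
]

# Canonical parameter order.  This order is load-bearing: it defines the
# layout of the packed array handed to the compiled right-hand side.
#
# The core and shell clock constants are the ancestor interlocked-feedback
# clock model uniformly scaled by 1.02 (core) and 1.14 (shell); the scaled
# values are kept at full precision here (printing them rounded to two
# decimals shifts the intrinsic periods by ~0.5 h).  Hill exponents are
# dimensionless and are not scaled.  The independently estimated constants
# (couplings, light input, neurotransmitter turnover) are exact as
# published.
_CORE_SCALE = 1.02
_SHELL_SCALE = 1.14

_DEFAULTS: dict[str, float] = {
    # --- SCN core ---
    "v_1bm": 9.0 * _CORE_SCALE,    # nM/h, maximal Per/Cry transcription rate
    "k_1bm": 1.0 * _CORE_SCALE,    # nM, Michaelis constant of Per/Cry transcription
    "k_1im": 0.56 * _CORE_SCALE,   # nM, inhibition constant of Per/Cry transcription
    "v_c1": 0.1,     # VIP coupling strength within the core
    "c_m": 1.0,      # Hill coefficient, VIP activation (core)
    "p_m": 8.0,      # Hill coefficient, Per/Cry auto-inhibition
    "k_1dm": 0.12 * _CORE_SCALE,   # 1/h, Per/Cry mRNA degradation
    "v_l": 0.25,     # light sensitivity of the core (coupling axis)
    "K_l": 50.0,     # Michaelis constant of the photic input
    "k_2bm": 0.3 * _CORE_SCALE,    # 1/(nM h), PER/CRY complex formation
    "q_m": 2.0,      # PER/CRY complex stoichiometry
    "k_2dm": 0.05 * _CORE_SCALE,   # 1/h, cytoplasmic PER/CRY degradation
    "k_2tm": 0.24 * _CORE_SCALE,   # 1/h, PER/CRY nuclear import
    "k_3tm": 0.02 * _CORE_SCALE,   # 1/h, PER/CRY nuclear export
    "k_3dm": 0.12 * _CORE_SCALE,   # 1/h, nuclear PER/CRY degradation
    "v_4bm": 3.6 * _CORE_SCALE,    # nM/h, maximal Bmal1 transcription rate
    "k_4bm": 2.16 * _CORE_SCALE,   # nM^3, Michaelis constant of Bmal1 transcription
    "r_m": 3.0,      # Hill coefficient, Bmal1 activation
    "k_4dm": 0.75 * _CORE_SCALE,   # 1/h, Bmal1 mRNA degradation
    "k_5bm": 0.24 * _CORE_SCALE,   # 1/h, BMAL1 translation
    "k_5dm": 0.06 * _CORE_SCALE,   # 1/h, cytoplasmic BMAL1 degradation
    "k_5tm": 0.45 * _CORE_SCALE,   # 1/h, BMAL1 nuclear import
    "k_6tm": 0.06 * _CORE_SCALE,   # 1/h, BMAL1 nuclear export
    "k_6dm": 0.12 * _CORE_SCALE,   # 1/h, nuclear BMAL1 degradation
    "k_6pm": 0.09 * _CORE_SCALE,   # 1/h, CLOCK/BMAL1 activation
    "k_7pm": 0.003 * _CORE_SCALE,  # 1/h, CLOCK/BMAL1 deactivation
    "k_7dm": 0.009 * _CORE_SCALE,  # 1/h, CLOCK/BMAL1 degradation
    "k_vs1": 1.5,    # 1/h, VIP synthesis upon PER/CRY activity
    "k_dv1": 1.5,    # 1/h, VIP degradation
    # --- SCN shell ---
    "v_1be": 9.0 * _SHELL_SCALE,
    "k_1be": 1.0 * _SHELL_SCALE,
    "k_1ie": 0.56 * _SHELL_SCALE,
    "v_c2": 1.01,    # VIP coupling strength onto the shell (coupling axis)
    "c_e": 3.0,      # Hill coefficient, VIP activation (shell)
    "p_e": 9.0,      # Hill coefficient, Per/Cry auto-inhibition
    "k_1de": 0.12 * _SHELL_SCALE,
    "k_2be": 0.3 * _SHELL_SCALE,
    "q_e": 2.0,
    "k_2de": 0.05 * _SHELL_SCALE,
    "k_2te": 0.24 * _SHELL_SCALE,
    "k_3te": 0.02 * _SHELL_SCALE,
    "k_3de": 0.12 * _SHELL_SCALE,
    "v_4be": 3.6 * _SHELL_SCALE,
    "k_4be": 2.16 * _SHELL_SCALE,
    "r_e": 3.0,
    "k_4de": 0.75 * _SHELL_SCALE,
    "k_5be": 0.24 * _SHELL_SCALE,
    "k_5de": 0.06 * _SHELL_SCALE,
    "k_5te": 0.45 * _SHELL_SCALE,
    "k_6te": 0.06 * _SHELL_SCALE,
    "k_6de": 0.12 * _SHELL_SCALE,
    "k_6pe": 0.09 * _SHELL_SCALE,
    "k_7pe": 0.003 * _SHELL_SCALE,
    "k_7de": 0.009 * _SHELL_SCALE,
    "k_vs2": 1.0,    # 1/h, AVP synthesis upon shell PER/CRY activity
    "k_dv2": 1.0,    # 1/h, AVP degradation
    # --- HPA axis ---
    "k_p1": 0.38,    # uM/h, zero-order CRH synthesis
    "K_p1": 6.54,    # uM, hypothalamic negative feedback constant
    "V_d1": 0.35,    # uM/h, CRH degradation capacity
    "K_d1": 4.39,    # uM, CRH degradation Michaelis constant
    "v_coe": 0.85,   # AVP coupling strength onto the HPA axis (coupling axis)
    "s": 3.0,        # Hill coefficient, AVP receptor saturation
    "k_p2": 0.46,    # uM/h, ACTH synthesis
    "K_p2": 1.63,    # uM, pituitary negative feedback constant
    "V_d2": 1.0,     # uM/h, ACTH degradation capacity
    "K_d2": 0.85,    # uM, ACTH degradation Michaelis constant
    "k_p3": 0.73,    # 1/h, adrenal feedforward sensitivity
    "V_d3": 0.72,    # uM/h, CORT degradation capacity
    "K_d3": 0.18,    # uM, CORT degradation Michaelis constant
    "k_syn_GRm": 2.9,   # fmol/g/h, GR mRNA synthesis
    "k_syn_GR": 1.2,    # 1/h per GR-mRNA unit, GR translation (resolved value)
    "r_f": 0.49,        # GR recycle fraction, nucleus -> cytoplasm
    "k_re": 0.57,       # 1/h, GR recycling rate
    "k_on": 0.00329,    # L/(nmol h), CORT-GR binding
    "k_deg_GR": 0.06,   # 1/h, free GR degradation
    "k_deg_GRm": 0.11,  # 1/h, GR mRNA degradation (resolved value)
    "k_T": 0.63,        # 1/h, GR-complex nuclear translocation
    # Half-max nuclear complex for GR-mRNA repression; not part of the
    # published parameter table.  Calibrated once at the coupled operating
    # point so that the AVP-driven axis phase-locks 1:1 to the entrained
    # SCN and corticosterone peaks at the onset of the dark period (ZT 12).
    "IC50_GRm": 12.0,   # fmol/g
}

PARAM_NAMES: tuple[str, ...] = tuple(_DEFAULTS)
COUPLING_NAMES: tuple[str, str, str] = ("v_l", "v_c2", "v_coe")

_HILL_NAMES = ("c_m", "p_m", "q_m", "r_m", "c_e", "p_e", "q_e", "r_e", "s")


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bag of all model constants.

    Construct with :func:`nominal_parameters` and derive variants with
    :meth:`with_updates` (e.g. ``p.with_updates(v_l=0.3)``).
    """

    values: dict[str, float] = field(default_factory=lambda: dict(_DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}; "
                           f"valid names are {list(PARAM_NAMES)}")
        missing = set(PARAM_NAMES) - set(self.values)
        if missing:
            raise KeyError(f"missing parameter(s): {sorted(missing)}")
        for name, v in self.values.items():
            v = float(v)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
            if name in _HILL_NAMES and v < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1, got {v}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def with_updates(self, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        for k, v in updates.items():
            if k not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[k] = float(v)
        return ParameterSet(vals)

    def uncoupled(self) -> "ParameterSet":
        """All three inter-compartment couplings zeroed (intrinsic systems)."""
        return self.with_updates(v_l=0.0, v_c2=0.0, v_coe=0.0)

    @property
    def couplings(self) -> tuple[float, float, float]:
        return tuple(self[k] for k in COUPLING_NAMES)

    def to_array(self) -> np.ndarray:
        """Pack into the canonical order consumed by the compiled RHS."""
        return np.array([self.values[k] for k in PARAM_NAMES], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {k: float(self.values[k]) for k in PARAM_NAMES}

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, mapping: dict[str, float],
                  base: "ParameterSet | None" = None) -> "ParameterSet":
        """Build from a flat mapping; missing keys fall back to ``base``."""
        base_vals = dict(_DEFAULTS) if base is None else dict(base.values)
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        base_vals.update({k: float(v) for k, v in mapping.items()})
        return cls(base_vals)

    @classmethod
    def from_yaml(cls, text: str, base: "ParameterSet | None" = None) -> "ParameterSet":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("parameter file must be a flat key: value mapping")
        return cls.from_dict(data, base=base)


@dataclass(frozen=True)
class CompartmentMask:
    """Flags selecting which inter-compartment couplings are active.

    Disabling a flag is exactly equivalent to zeroing the corresponding
    coupling constant (``v_l``, ``v_c2``, ``v_coe``).
    """

    light: bool = True
    vip_to_shell: bool = True
    avp_to_hpa: bool = True

    def apply(self, params: ParameterSet) -> ParameterSet:
        updates: dict[str, float] = {}
        if not self.light:
            updates["v_l"] = 0.0
        if not self.vip_to_shell:
            updates["v_c2"] = 0.0
        if not self.avp_to_hpa:
            updates["v_coe"] = 0.0
        return params.with_updates(**updates) if updates else params


def nominal_parameters() -> ParameterSet:
    """The published nominal parameter set (the calibrated individual)."""
    return ParameterSet(dict(_DEFAULTS))


def bundled_table_defaults() -> ParameterSet:
    """Load the bundled ``table1.yaml`` default parameter file."""
    text = resources.files("scnhpa.data").joinpath("table1.yaml").read_text()
    return ParameterSet.from_yaml(text)
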