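"""Parameter vectors for the closed-loop cardiovascular models.

Four model variants are supported: one-chamber (``1ch``) and four-chamber
(``4ch``) lumped-parameter circulations, each with or without baroreflex
regulation.  This module owns the base parameter values, their validation
invariants, the flat free-parameter ordering used by the sensitivity drivers,
and (de)serialisation to a YAML config dialect.

Units follow the clinical 0D-modelling convention: pressures in mmHg, volumes
in ml, flows in ml/s, compliances in ml/mmHg, resistances in mmHg*s/ml,
elastances in mmHg/ml, neural frequencies in spikes/s, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ChamberParams",
    "CirculationParams",
    "EffectorSpec",
    "BaroParams",
    "ModelParameters",
    "default_parameters",
    "flatten",
    "unflatten",
    "perturbation_bounds",
    "get_value",
    "set_value",
    "PARAMETER_DIMENSIONS",
]

#: Expected free-parameter dimensions per (variant, regulated).
PARAMETER_DIMENSIONS = {
    ("1ch", True): 36,
    ("1ch", False): 9,
    ("4ch", True): 51,
    ("4ch", False): 22,
}


class ParameterError(ValueError):
    """Raised when a parameter set violates a structural invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class ChamberParams:
    """Time-varying elastance chamber (double-cosine activation).

    Timing is stored as dimensionless fractions of the current heart period;
    atrial systole wraps around the cycle boundary (tau_init_frac 0.92,
    tau_s2_frac 1.0), so validity is checked on wrap-normalised durations.
    """

    e_min: float
    e_max: float
    tau_init_frac: float
    tau_s1_frac: float
    tau_s2_frac: float
    v0: float = 0.0

    def validate(self) -> None:
        _require(0.0 < self.e_min <= self.e_max, "need 0 < E_min <= E_max")
        _require(self.v0 >= 0.0, "V0 must be non-negative")
        rise, fall = self.normalized_phases()
        _require(rise > 0.0, "systolic rise duration must be positive")
        _require(fall > 0.0, "systolic fall duration must be positive")
        _require(rise + fall <= 1.0 + 1e-12,
                 "systolic phases must fit within one cycle")

    def normalized_phases(self) -> tuple[float, float]:
        """Wrap-normalised (rise, fall) durations as fractions of the cycle."""
        rise = (self.tau_s1_frac - self.tau_init_frac) % 1.0
        fall = (self.tau_s2_frac - self.tau_s1_frac) % 1.0
        # a chamber with s2 == init + 1 (full-cycle activation support) is
        # allowed; the modulo above would fold an exact 1.0 to 0.0
        if rise == 0.0 and self.tau_s1_frac != self.tau_init_frac:
            rise = 1.0
        if fall == 0.0 and self.tau_s2_frac != self.tau_s1_frac:
            fall = 1.0
        return rise, fall


@dataclass
class CirculationParams:
    """Passive-circulation constants (Windkessel compliances/resistances)."""

    c_art: float
    c_ven: float
    r_sys: float
    r_mv: float
    r_av: float
    r_tv: float | None = None
    r_pv: float | None = None
    c_pula: float | None = None
    c_pulv: float | None = None
    r_pul: float | None = None
    v_unv_init: float = 0.0

    def validate(self, variant: str) -> None:
        for name in ("c_art", "c_ven", "r_sys", "r_mv", "r_av"):
            _require(getattr(self, name) > 0.0, f"{name} must be positive")
        _require(self.v_unv_init >= 0.0, "v_unv_init must be non-negative")
        if variant == "4ch":
            for name in ("r_tv", "r_pv", "c_pula", "c_pulv", "r_pul"):
                v = getattr(self, name)
                _require(v is not None and v > 0.0,
                         f"{name} must be positive for the 4ch variant")


@dataclass
class EffectorSpec:
    """A baroreflex effector pathway: gain, time constant, transport delay.

    ``update_mode`` is ``beat_to_beat`` for heart period and ventricular
    contractility (held constant within a beat, promoted at beat onset) and
    ``continuous`` for systemic resistance and venous unstressed volume.
    """

    target: str  # tau_hr | e_lvmax | e_rvmax | r_sys | v_unv
    arc: str  # sympathetic | vagal
    g: float
    tau: float
    d: float
    update_mode: str

    def validate(self) -> None:
        _require(self.tau > 0.0, f"effector {self.target}: tau must be > 0")
        _require(self.d >= 0.0, f"effector {self.target}: delay must be >= 0")
        _require(self.arc in ("sympathetic", "vagal"), "unknown arc")
        beat = self.target in ("tau_hr", "e_lvmax", "e_rvmax")
        expected = "beat_to_beat" if beat else "continuous"
        _require(self.update_mode == expected,
                 f"effector {self.target}: update_mode must be {expected}")


@dataclass
class BaroParams:
    """Afferent/efferent static characteristics of the baroreflex arc."""

    p_n: float
    f_min: float
    f_max: float
    k_a: float
    f_cs0: float
    tau_p: float
    tau_z: float
    f_es_inf: float
    f_es_0: float
    f_es_min: float
    k_es: float
    f_ev_0: float
    f_ev_inf: float
    k_ev: float
    effectors: list[EffectorSpec] = field(default_factory=list)

    def validate(self) -> None:
        _require(self.f_min < self.f_max, "need f_min < f_max")
        _require(self.f_es_inf < self.f_es_0, "need f_es_inf < f_es_0")
        _require(self.f_ev_0 < self.f_ev_inf, "need f_ev_0 < f_ev_inf")
        for name in ("k_a", "k_es", "k_ev", "tau_p", "tau_z"):
            _require(getattr(self, name) > 0.0, f"{name} must be positive")
        tau_specs = [e for e in self.effectors if e.target == "tau_hr"]
        _require(len(tau_specs) == 2 and
                 {e.arc for e in tau_specs} == {"sympathetic", "vagal"},
                 "tau_hr needs one sympathetic and one vagal effector")
        for e in self.effectors:
            e.validate()

    def effector(self, target: str, arc: str | None = None) -> EffectorSpec:
        for e in self.effectors:
            if e.target == target and (arc is None or e.arc == arc):
                return e
        raise KeyError(f"no effector for target={target} arc={arc}")


@dataclass
class ModelParameters:
    """Complete input-parameter vector for one model variant."""

    variant: str  # "1ch" | "4ch"
    regulated: bool
    tau_hr0: float
    mcfp: float
    chambers: dict[str, ChamberParams]
    circulation: CirculationParams
    baro: BaroParams | None = None
    free_parameter_order: list[str] = field(default_factory=list)
    #: Initial left-ventricular volume (ml).  Together with the mcfp-uniform
    #: passive pressures this sets the conserved total stressed volume of the
    #: closed loop, which the printed tables do not determine.  ``None``
    #: selects the variant default (see :func:`default_parameters`).
    v_lv_init: float | None = None

    def validate(self) -> "ModelParameters":
        _require(self.variant in ("1ch", "4ch"), f"unknown variant {self.variant!r}")
        _require(self.tau_hr0 > 0.0, "tau_hr0 must be positive")
        _require(self.mcfp > 0.0, "mcfp must be positive")
        expected = {"lv"} if self.variant == "1ch" else {"lv", "rv", "la", "ra"}
        _require(set(self.chambers) == expected,
                 f"variant {self.variant} needs chambers {sorted(expected)}")
        for ch in self.chambers.values():
            ch.validate()
        self.circulation.validate(self.variant)
        if self.regulated:
            _require(self.baro is not None, "regulated model needs baro params")
            self.baro.validate()
            targets = {e.target for e in self.baro.effectors}
            want = {"tau_hr", "e_lvmax", "r_sys"}
            if self.variant == "4ch":
                want |= {"e_rvmax", "v_unv"}
            _require(targets == want,
                     f"variant {self.variant} needs effectors {sorted(want)}")
        if self.v_lv_init is not None:
            _require(self.v_lv_init > 0.0, "v_lv_init must be positive")
        n = PARAMETER_DIMENSIONS[(self.variant, self.regulated)]
        _require(len(self.free_parameter_order) == n,
                 f"free_parameter_order must have {n} entries, "
                 f"got {len(self.free_parameter_order)}")
        return self

    def copy(self) -> "ModelParameters":
        chambers = {k: replace(v) for k, v in self.chambers.items()}
        circulation = replace(self.circulation)
        baro = None
        if self.baro is not None:
            baro = replace(self.baro,
                           effectors=[replace(e) for e in self.baro.effectors])
        return ModelParameters(self.variant, self.regulated, self.tau_hr0,
                               self.mcfp, chambers, circulation, baro,
                               list(self.free_parameter_order),
                               self.v_lv_init)


# ---------------------------------------------------------------------------
# Base values
# ---------------------------------------------------------------------------

_VENTRICULAR_TIMING = dict(tau_init_frac=0.0, tau_s1_frac=0.30, tau_s2_frac=0.45)
_ATRIAL_TIMING = dict(tau_init_frac=0.92, tau_s1_frac=0.96, tau_s2_frac=1.0)

#: Default initial LV volume (ml) of the one-chamber model.  The tables fix
#: every rate constant but not the conserved total stressed volume of the
#: closed loop; this value (total stressed volume ~260 ml) is identified once
#: from the published regulated steady-state operating point (tau_HR 0.906 s,
#: E_LVmax 2.48, R_sys 2.386) and then treated as a structural constant.  The
#: four-chamber model instead starts from the exactly uniform stopped state
#: (V_LV = mcfp/E_LVmin): its unstressed-volume regulation makes the
#: operating point robust to the initial volume.
DEFAULT_V_LV_INIT_1CH = 164.0


def _base_effectors(variant: str) -> list[EffectorSpec]:
    eff = [
        EffectorSpec("e_lvmax", "sympathetic", 0.475, 8.0, 2.0, "beat_to_beat"),
        EffectorSpec("r_sys", "sympathetic", 0.695, 6.0, 2.0, "continuous"),
        EffectorSpec("tau_hr", "sympathetic", -0.130, 2.0, 2.0, "beat_to_beat"),
        EffectorSpec("tau_hr", "vagal", 0.090, 1.5, 0.2, "beat_to_beat"),
    ]
    if variant == "4ch":
        eff.insert(1, EffectorSpec("e_rvmax", "sympathetic", 0.282, 8.0, 2.0,
                                   "beat_to_beat"))
        eff.insert(3, EffectorSpec("v_unv", "sympathetic", -199.0, 20.0, 5.0,
                                   "continuous"))
    return eff


def _base_baro(variant: str) -> BaroParams:
    return BaroParams(
        p_n=92.0, f_min=2.52, f_max=47.78, k_a=11.758, f_cs0=25.0,
        tau_p=2.076, tau_z=6.370,
        f_es_inf=2.10, f_es_0=16.110, f_es_min=2.66, k_es=0.0675,
        f_ev_0=3.20, f_ev_inf=6.30, k_ev=7.06,
        effectors=_base_effectors(variant),
    )


# Free-parameter orderings.  The printed dimensions (36/9/51/22) constrain but
# do not uniquely determine the perturbed sets; the reconciliation rules are:
#   * tau_initV (base 0) and V_unV_init (base 0) are structural everywhere;
#   * unregulated analyses drop tau_HR0 (heart period is likewise dropped from
#     the unregulated output list, because nothing regulates it);
#   * the regulated 4CH drops every cardiac timing fraction (they destabilise
#     the four-chamber analysis);
#   * tau_S2A (base 1.0*tau) and tau_S1A (0.96*tau) cannot move +10% without
#     breaking the activation ordering, so they are never perturbed;
#   * mcfp is structural except in the unregulated 4CH, where total blood
#     volume is a genuine free input and is needed to reach the printed count.
# See docs/methods.md for the full published lists.

_BARO_COMMON = [
    "p_n", "f_min", "f_max", "k_a", "f_cs0", "tau_p", "tau_z",
    "f_es_inf", "f_es_0", "f_es_min", "k_es", "f_ev_0", "f_ev_inf", "k_ev",
]
_EFFECTOR_1CH = [
    "g_emax_lv", "tau_emax_lv", "d_emax_lv",
    "g_rsys", "tau_rsys", "d_rsys",
    "g_tau_s", "tau_tau_s", "d_tau_s",
    "g_tau_v", "tau_tau_v", "d_tau_v",
]
_EFFECTOR_4CH = [
    "g_emax_lv", "tau_emax_lv", "d_emax_lv",
    "g_emax_rv", "tau_emax_rv", "d_emax_rv",
    "g_rsys", "tau_rsys", "d_rsys",
    "g_vunv", "tau_vunv", "d_vunv",
    "g_tau_s", "tau_tau_s", "d_tau_s",
    "g_tau_v", "tau_tau_v", "d_tau_v",
]

_MECH_1CH = ["e_lvmin", "e_lvmax", "tau_s1v", "tau_s2v",
             "r_mv", "r_av", "c_art", "r_sys", "c_ven"]
_ELASTANCES_4CH = ["e_lvmin", "e_lvmax", "e_rvmin", "e_rvmax",
                   "e_lamin", "e_lamax", "e_ramin", "e_ramax"]
_VALVES_4CH = ["r_mv", "r_av", "r_tv", "r_pv"]
_CIRC_4CH = ["c_art", "r_sys", "c_ven", "c_pula", "r_pul", "c_pulv"]

_FREE_ORDER = {
    ("1ch", True): ["tau_hr0"] + _MECH_1CH + _BARO_COMMON + _EFFECTOR_1CH,
    ("1ch", False): list(_MECH_1CH),
    ("4ch", True): (["tau_hr0"] + _ELASTANCES_4CH + _VALVES_4CH + _CIRC_4CH
                    + _BARO_COMMON + _EFFECTOR_4CH),
    ("4ch", False): (["mcfp"] + _ELASTANCES_4CH
                     + ["tau_s1v", "tau_s2v", "tau_inita"]
                     + _VALVES_4CH + _CIRC_4CH),
}


def default_parameters(variant: str, regulated: bool) -> ModelParameters:
    """Base parameter set for a model variant.

    The unregulated variants return the same base mechanical values as the
    regulated ones; deriving the *equivalent* unregulated state (overriding
    effector base values with their regulated steady-state means) is a
    separate operation, :func:`baroloop.simulator.derive_unregulated_equivalent`.
    """
    variant = str(variant).lower()
    if variant not in ("1ch", "4ch"):
        raise ParameterError(f"unknown variant {variant!r}")
    if variant == "1ch":
        chambers = {"lv": ChamberParams(0.06, 2.00, **_VENTRICULAR_TIMING)}
        circulation = CirculationParams(
            c_art=1.13, c_ven=11.00, r_sys=1.663, r_mv=0.06, r_av=0.033)
        mcfp = 8.0
    else:
        chambers = {
            "lv": ChamberParams(0.06, 2.00, **_VENTRICULAR_TIMING),
            "rv": ChamberParams(0.15, 1.75, **_VENTRICULAR_TIMING),
            "la": ChamberParams(0.15, 0.25, **_ATRIAL_TIMING),
            "ra": ChamberParams(0.15, 0.25, **_ATRIAL_TIMING),
        }
        circulation = CirculationParams(
            c_art=1.13, c_ven=20.50, r_sys=1.663,
            r_mv=0.0025, r_av=0.0025, r_tv=0.0025, r_pv=0.0025,
            c_pula=4.50, c_pulv=20.50, r_pul=0.30, v_unv_init=0.0)
        mcfp = 6.0
    params = ModelParameters(
        variant=variant,
        regulated=bool(regulated),
        tau_hr0=0.58,
        mcfp=mcfp,
        chambers=chambers,
        circulation=circulation,
        baro=_base_baro(variant) if regulated else None,
        free_parameter_order=list(_FREE_ORDER[(variant, bool(regulated))]),
    )
    return params.validate()


# ---------------------------------------------------------------------------
# Named scalar access
# ---------------------------------------------------------------------------

_CHAMBER_SCALARS = {
    "e_lvmin": ("lv", "e_min"), "e_lvmax": ("lv", "e_max"),
    "e_rvmin": ("rv", "e_min"), "e_rvmax": ("rv", "e_max"),
    "e_lamin": ("la", "e_min"), "e_lamax": ("la", "e_max"),
    "e_ramin": ("ra", "e_min"), "e_ramax": ("ra", "e_max"),
}
# timing names address both ventricles (or both atria) at once
_TIMING_SCALARS = {
    "tau_initv": (("lv", "rv"), "tau_init_frac"),
    "tau_s1v": (("lv", "rv"), "tau_s1_frac"),
    "tau_s2v": (("lv", "rv"), "tau_s2_frac"),
    "tau_inita": (("la", "ra"), "tau_init_frac"),
    "tau_s1a": (("la", "ra"), "tau_s1_frac"),
    "tau_s2a": (("la", "ra"), "tau_s2_frac"),
}
_CIRC_SCALARS = {n: n for n in (
    "c_art", "c_ven", "r_sys", "r_mv", "r_av", "r_tv", "r_pv",
    "c_pula", "c_pulv", "r_pul", "v_unv_init")}
_BARO_SCALARS = {n: n for n in _BARO_COMMON}
_EFFECTOR_SCALARS = {
    "g_emax_lv": ("e_lvmax", None, "g"),
    "tau_emax_lv": ("e_lvmax", None, "tau"),
    "d_emax_lv": ("e_lvmax", None, "d"),
    "g_emax_rv": ("e_rvmax", None, "g"),
    "tau_emax_rv": ("e_rvmax", None, "tau"),
    "d_emax_rv": ("e_rvmax", None, "d"),
    "g_rsys": ("r_sys", None, "g"),
    "tau_rsys": ("r_sys", None, "tau"),
    "d_rsys": ("r_sys", None, "d"),
    "g_vunv": ("v_unv", None, "g"),
    "tau_vunv": ("v_unv", None, "tau"),
    "d_vunv": ("v_unv", None, "d"),
    "g_tau_s": ("tau_hr", "sympathetic", "g"),
    "tau_tau_s": ("tau_hr", "sympathetic", "tau"),
    "d_tau_s": ("tau_hr", "sympathetic", "d"),
    "g_tau_v": ("tau_hr", "vagal", "g"),
    "tau_tau_v": ("tau_hr", "vagal", "tau"),
    "d_tau_v": ("tau_hr", "vagal", "d"),
}


def scalar_names(params: ModelParameters) -> list[str]:
    """All addressable scalar names for this variant (superset of the free set)."""
    names = ["tau_hr0", "mcfp"]
    if params.variant == "1ch":
        names += ["e_lvmin", "e_lvmax", "tau_initv", "tau_s1v", "tau_s2v",
                  "r_mv", "r_av", "c_art", "r_sys", "c_ven"]
    else:
        names += (_ELASTANCES_4CH
                  + ["tau_initv", "tau_s1v", "tau_s2v",
                     "tau_inita", "tau_s1a", "tau_s2a"]
                  + _VALVES_4CH + _CIRC_4CH + ["v_unv_init"])
    if params.regulated:
        names += _BARO_COMMON
        names += _EFFECTOR_1CH if params.variant == "1ch" else _EFFECTOR_4CH
    return names


def get_value(params: ModelParameters, name: str) -> float:
    if name == "tau_hr0":
        return params.tau_hr0
    if name == "mcfp":
        return params.mcfp
    if name in _CHAMBER_SCALARS:
        ch, attr = _CHAMBER_SCALARS[name]
        return getattr(params.chambers[ch], attr)
    if name in _TIMING_SCALARS:
        chs, attr = _TIMING_SCALARS[name]
        return getattr(params.chambers[chs[0]], attr)
    if name in _CIRC_SCALARS:
        return getattr(params.circulation, name)
    if name in _BARO_SCALARS:
        return getattr(params.baro, name)
    if name in _EFFECTOR_SCALARS:
        target, arc, attr = _EFFECTOR_SCALARS[name]
        return getattr(params.baro.effector(target, arc), attr)
    raise KeyError(f"unknown parameter name {name!r}")


def set_value(params: ModelParameters, name: str, value: float) -> None:
    value = float(value)
    if name == "tau_hr0":
        params.tau_hr0 = value
    elif name == "mcfp":
        params.mcfp = value
    elif name in _CHAMBER_SCALARS:
        ch, attr = _CHAMBER_SCALARS[name]
        setattr(params.chambers[ch], attr, value)
    elif name in _TIMING_SCALARS:
        chs, attr = _TIMING_SCALARS[name]
        for ch in chs:
            if ch in params.chambers:
                setattr(params.chambers[ch], attr, value)
    elif name in _CIRC_SCALARS:
        setattr(params.circulation, name, value)
    elif name in _BARO_SCALARS:
        setattr(params.baro, name, value)
    elif name in _EFFECTOR_SCALARS:
        target, arc, attr = _EFFECTOR_SCALARS[name]
        setattr(params.baro.effector(target, arc), attr, value)
    else:
        raise KeyError(f"unknown parameter name {name!r}")


# ---------------------------------------------------------------------------
# Flatten / unflatten / bounds
# ---------------------------------------------------------------------------

def flatten(params: ModelParameters) -> np.ndarray:
    """Free parameters as an ordered vector (``free_parameter_order``)."""
    return np.array([get_value(params, n) for n in params.free_parameter_order],
                    dtype=float)


def unflatten(vector: Iterable[float], template: ModelParameters) -> ModelParameters:
    """Rebuild a validated parameter set from a free-parameter vector."""
    vector = np.asarray(list(vector), dtype=float)
    order = template.free_parameter_order
    if vector.shape != (len(order),):
        raise ParameterError(
            f"expected a vector of length {len(order)}, got shape {vector.shape}")
    out = template.copy()
    for name, value in zip(order, vector):
        set_value(out, name, value)
    return out.validate()


def perturbation_bounds(params: ModelParameters, fraction: float,
                        allow_degenerate: bool = False) -> np.ndarray:
    """Per-parameter (low, high) box of +-``fraction`` around the base values.

    For negative base values (the sympathetic heart-period gain and the
    unstressed-volume gain) the interval is ordered numerically so samplers
    always receive low < high.
    """
    fraction = float(fraction)
    if fraction == 0.0 and allow_degenerate:
        base = flatten(params)
        return np.column_stack([base, base])
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must lie in (0, 1)")
    base = flatten(params)
    lo = base * (1.0 - fraction)
    hi = base * (1.0 + fraction)
    return np.column_stack([np.minimum(lo, hi), np.maximum(lo, hi)])


# ---------------------------------------------------------------------------
# Config serialization (YAML dialect)
# ---------------------------------------------------------------------------

def params_to_dict(params: ModelParameters) -> dict:
    mech = {}
    baro = {}
    for name in scalar_names(params):
        section = baro if (name in _BARO_SCALARS or name in _EFFECTOR_SCALARS) \
            else mech
        section[name] = get_value(params, name)
    out = {"model": {"variant": params.variant, "regulated": params.regulated},
           "mechanical": mech}
    if params.regulated:
        out["baroreflex"] = baro
    return out


def params_from_dict(data: dict) -> ModelParameters:
    known_sections = {"model", "mechanical", "baroreflex",
                      "simulation", "sensitivity"}
    unknown = set(data) - known_sections
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")
    model = dict(data.get("model", {}))
    variant = str(model.pop("variant", "1ch")).lower()
    regulated = bool(model.pop("regulated", True))
    if model:
        raise ParameterError(f"unknown keys in 'model': {sorted(model)}")
    params = default_parameters(variant, regulated)
    valid = set(scalar_names(params))
    # a config written for the regulated variant may be re-used with the
    # regulation switched off; its baroreflex section is then inert
    sections = ("mechanical", "baroreflex") if regulated else ("mechanical",)
    for section in sections:
        for name, value in dict(data.get(section, {})).items():
            if name not in valid:
                raise ParameterError(
                    f"unknown parameter {name!r} in section {section!r}")
            set_value(params, name, float(value))
    return params.validate()
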