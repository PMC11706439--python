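"""Mechanical building blocks of the 0D circulation.

Double-cosine time-varying elastance chambers, Ohmic diode valves and passive
CRC (compliance-resistance-compliance) Windkessel compartments, assembled into
the unregulated one-chamber and four-chamber right-hand sides.

All chamber unstressed volumes are zero, which lets chamber volume states be
eliminated: with P = E(t) * V the ventricular pressure obeys
``dP/dt = (E'/E) P + E (Q_in - Q_out)``.  Atria share a pressure node with the
adjacent venous compliance (P_RA = P_V, P_LA = P_pulV), giving the merged
dynamics implemented in :func:`merged_atrial_rate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .parameters import ChamberParams, ModelParameters

__all__ = [
    "CompartmentState",
    "ActivationClock",
    "activation",
    "activation_slope",
    "elastance",
    "elastance_slope",
    "valve_flow",
    "merged_atrial_rate",
    "rhs_unregulated",
    "state_names",
    "total_stressed_volume",
]


@dataclass
class CompartmentState:
    """Instantaneous state of one compartment (pressure mmHg, stressed volume
    ml, inlet flow ml/s).  For a passive linear compartment V_s = C * P."""

    p: float
    v_s: float
    q_in: float


@dataclass
class ActivationClock:
    """Time since the current beat onset and the current heart period (s)."""

    t_cycle: float
    tau: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_cycle < self.tau):
            raise ValueError("need 0 <= t_cycle < tau")


# ---------------------------------------------------------------------------
# numba cores (shared by the python API and the production integrator)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _activation(x: float, tes: float, tep: float) -> float:
    if x < 0.0:
        return 0.0
    if x < tes:
        return 0.5 * (1.0 - math.cos(math.pi * x / tes))
    if x < tep:
        return 0.5 * (1.0 + math.cos(math.pi * (x - tes) / (tep - tes)))
    return 0.0


@njit(cache=True)
def _activation_slope(x: float, tes: float, tep: float) -> float:
    if x < 0.0:
        return 0.0
    if x < tes:
        return 0.5 * math.pi / tes * math.sin(math.pi * x / tes)
    if x < tep:
        return -0.5 * math.pi / (tep - tes) * math.sin(
            math.pi * (x - tes) / (tep - tes))
    return 0.0


@njit(cache=True)
def _elastance_pair(t_cycle, tau, e_min, e_max, f_init, f_s1, f_s2):
    """(E, dE/dt) of a chamber at cycle time t_cycle for heart period tau.

    Timing is given as fractions of tau; the activation support is shifted by
    f_init and wrapped modulo the cycle, so atrial systole spanning the cycle
    boundary is handled by the same expression.
    """
    rise = (f_s1 - f_init) % 1.0
    fall = (f_s2 - f_s1) % 1.0
    x = (t_cycle / tau - f_init) % 1.0
    e = _activation(x, rise, fall + rise)
    de = _activation_slope(x, rise, fall + rise) / tau
    amp = e_max - e_min
    return amp * e + e_min, amp * de


@njit(cache=True)
def _valve(p_up: float, p_down: float, r_val: float) -> float:
    dp = p_up - p_down
    if dp > 0.0:
        return dp / r_val
    return dp / (1000.0 * r_val)


# ---------------------------------------------------------------------------
# python API
# ---------------------------------------------------------------------------

def activation(t_cycle: float, tau_es: float, tau_ep: float) -> float:
    """Dimensionless double-cosine activation in [0, 1].

    Rising half-cosine on [0, tau_es), falling on [tau_es, tau_ep), zero
    afterwards; continuous everywhere.
    """
    if not (0.0 < tau_es < tau_ep):
        raise ValueError("need 0 < tau_es < tau_ep")
    if t_cycle < 0.0:
        raise ValueError("t_cycle must be non-negative")
    return float(_activation(t_cycle, tau_es, tau_ep))


def activation_slope(t_cycle: float, tau_es: float, tau_ep: float) -> float:
    """Time derivative of :func:`activation`."""
    if not (0.0 < tau_es < tau_ep):
        raise ValueError("need 0 < tau_es < tau_ep")
    return float(_activation_slope(t_cycle, tau_es, tau_ep))


def elastance(t_cycle: float, chamber: ChamberParams, tau: float) -> float:
    """Chamber elastance (mmHg/ml) at cycle time ``t_cycle`` for period ``tau``."""
    e, _ = _elastance_pair(t_cycle % tau, tau, chamber.e_min, chamber.e_max,
                           chamber.tau_init_frac, chamber.tau_s1_frac,
                           chamber.tau_s2_frac)
    return float(e)


def elastance_slope(t_cycle: float, chamber: ChamberParams, tau: float) -> float:
    """dE/dt (mmHg/ml/s) at cycle time ``t_cycle``."""
    _, de = _elastance_pair(t_cycle % tau, tau, chamber.e_min, chamber.e_max,
                            chamber.tau_init_frac, chamber.tau_s1_frac,
                            chamber.tau_s2_frac)
    return float(de)


def valve_flow(p_up: float, p_down: float, r_val: float) -> float:
    """Diode valve flow (ml/s): Ohmic forward, 1000x resistance under reverse
    bias; both branches vanish at zero pressure gradient."""
    if r_val <= 0.0:
        raise ValueError("valve resistance must be positive")
    return float(_valve(p_up, p_down, r_val))


def merged_atrial_rate(p_node: float, e_a: float, de_a: float, c_par: float,
                       q_in: float, q_out: float,
                       dvol_injection: float = 0.0) -> float:
    """dP/dt of an atrium merged with a parallel venous compliance.

    Implements the combined compartment expression: the atrial elastance
    time-modulates the shared node, ``c_par`` is the parallel compliance and
    ``dvol_injection`` (ml/s) is the rate of volume entering the stressed pool
    from unstressed-volume regulation::

        dP/dt = E/(1 + C E) (q_in + injection - q_out) + E'/(E (1 + C E)) P
    """
    denom = 1.0 + c_par * e_a
    if denom <= 0.0:
        raise ValueError("non-physical merged compartment: 1 + C*E <= 0")
    return (e_a / denom * (q_in + dvol_injection - q_out)
            + de_a / (e_a * denom) * p_node)


def state_names(variant: str) -> list[str]:
    if variant == "1ch":
        return ["p_lv", "p_art", "p_ven"]
    return ["p_lv", "p_art", "p_ven", "p_rv", "p_pula", "p_pulv"]


def rhs_unregulated(state: np.ndarray, params: ModelParameters,
                    clock: ActivationClock) -> np.ndarray:
    """Time derivatives of the pressure states of the unregulated model.

    ``state`` follows :func:`state_names`; the venous node doubles as the
    right-atrial pressure and the pulmonary-venous node as the left-atrial
    pressure in the four-chamber variant.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    c = params.circulation
    tau = clock.tau
    tc = clock.t_cycle
    lv = params.chambers["lv"]
    e_lv, de_lv = _elastance_pair(tc, tau, lv.e_min, lv.e_max,
                                  lv.tau_init_frac, lv.tau_s1_frac,
                                  lv.tau_s2_frac)
    if params.variant == "1ch":
        p_lv, p_art, p_ven = state
        q_mv = _valve(p_ven, p_lv, c.r_mv)
        q_av = _valve(p_lv, p_art, c.r_av)
        q_sys = (p_art - p_ven) / c.r_sys
        return np.array([
            de_lv / e_lv * p_lv + e_lv * (q_mv - q_av),
            (q_av - q_sys) / c.c_art,
            (q_sys - q_mv) / c.c_ven,
        ])
    p_lv, p_art, p_ra, p_rv, p_pula, p_la = state
    rv = params.chambers["rv"]
    la = params.chambers["la"]
    ra = params.chambers["ra"]
    e_rv, de_rv = _elastance_pair(tc, tau, rv.e_min, rv.e_max,
                                  rv.tau_init_frac, rv.tau_s1_frac,
                                  rv.tau_s2_frac)
    e_la, de_la = _elastance_pair(tc, tau, la.e_min, la.e_max,
                                  la.tau_init_frac, la.tau_s1_frac,
                                  la.tau_s2_frac)
    e_ra, de_ra = _elastance_pair(tc, tau, ra.e_min, ra.e_max,
                                  ra.tau_init_frac, ra.tau_s1_frac,
                                  ra.tau_s2_frac)
    q_mv = _valve(p_la, p_lv, c.r_mv)
    q_av = _valve(p_lv, p_art, c.r_av)
    q_sys = (p_art - p_ra) / c.r_sys
    q_tv = _valve(p_ra, p_rv, c.r_tv)
    q_pv = _valve(p_rv, p_pula, c.r_pv)
    q_pul = (p_pula - p_la) / c.r_pul
    return np.array([
        de_lv / e_lv * p_lv + e_lv * (q_mv - q_av),
        (q_av - q_sys) / c.c_art,
        merged_atrial_rate(p_ra, e_ra, de_ra, c.c_ven, q_sys, q_tv),
        de_rv / e_rv * p_rv + e_rv * (q_tv - q_pv),
        (q_pv - q_pul) / c.c_pula,
        merged_atrial_rate(p_la, e_la, de_la, c.c_pulv, q_pul, q_mv),
    ])


def total_stressed_volume(state: np.ndarray, params: ModelParameters,
                          clock: ActivationClock) -> float:
    """Total stressed blood volume (ml) implied by the pressure state.

    For the closed unregulated loop this is conserved exactly by the dynamics;
    with unstressed-volume regulation the conserved quantity adds the venous
    unstressed-volume deviation (see :mod:`baroloop.baroreflex`).
    """
    state = np.asarray(state, dtype=float)
    c = params.circulation
    lv = params.chambers["lv"]
    tau, tc = clock.tau, clock.t_cycle
    e_lv, _ = _elastance_pair(tc, tau, lv.e_min, lv.e_max, lv.tau_init_frac,
                              lv.tau_s1_frac, lv.tau_s2_frac)
    if params.variant == "1ch":
        p_lv, p_art, p_ven = state
        return p_lv / e_lv + c.c_art * p_art + c.c_ven * p_ven
    p_lv, p_art, p_ra, p_rv, p_pula, p_la = state
    rv, la, ra = (params.chambers[k] for k in ("rv", "la", "ra"))
    e_rv, _ = _elastance_pair(tc, tau, rv.e_min, rv.e_max, rv.tau_init_frac,
                              rv.tau_s1_frac, rv.tau_s2_frac)
    e_la, _ = _elastance_pair(tc, tau, la.e_min, la.e_max, la.tau_init_frac,
                              la.tau_s1_frac, la.tau_s2_frac)
    e_ra, _ = _elastance_pair(tc, tau, ra.e_min, ra.e_max, ra.tau_init_frac,
                              ra.tau_s1_frac, ra.tau_s2_frac)
    return (p_lv / e_lv + p_rv / e_rv
            + c.c_art * p_art + c.c_pula * p_pula
            + p_ra / e_ra + c.c_ven * p_ra
            + p_la / e_la + c.c_pulv * p_la)
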