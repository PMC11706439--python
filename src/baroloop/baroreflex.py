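"""Baroreflex arc: afferent transduction, efferent static characteristics,
delayed first-order effector dynamics, beat-to-beat state promotion and
unstressed-volume regulation.

The arterial pressure of the mechanical model is the carotid-sinus surrogate.
It is low-pass/lead filtered into a control pressure (real pole tau_p, real
zero tau_z), transduced into an afferent spiking frequency by a sigmoid, and
split into antagonistic sympathetic (exponential decay) and vagal (sigmoid)
efferent frequencies.  Each effector pathway applies a transport delay, a
static characteristic (log for sympathetic pathways, linear for the vagal
one) and first-order relaxation.  Heart period receives the SUM of a
sympathetic and a vagal contribution, each with its own gain, time constant
and delay.

Heart period and ventricular contractility update beat-to-beat: their
absolute values are held constant within a beat and promoted at beat onset to
base + deviation.  The promotion is expressed as a narrow normalised-Gaussian
relaxation (the smooth representation of a Dirac impulse), so the closed-loop
system remains a plain delay-differential system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

from .parameters import BaroParams, EffectorSpec

__all__ = [
    "AfferentState",
    "EffectorState",
    "afferent_rate",
    "afferent_frequency",
    "sympathetic_frequency",
    "vagal_frequency",
    "sympathetic_static",
    "vagal_static",
    "effector_rate",
    "beat_promotion_rate",
    "unstressed_volume_coupling",
    "PROMOTION_AREA",
]

#: Dimensionless area of the promotion bump.  The held value relaxes to the
#: target with residual exp(-area), i.e. ~4e-18 here — far below the 1e-4
#: relative promotion tolerance.
PROMOTION_AREA = 40.0


@dataclass
class AfferentState:
    """Filtered control pressure (mmHg) sensed by the baroreceptors."""

    p_tilde: float


@dataclass
class EffectorState:
    """Deviation from base and, for beat-to-beat effectors, the held absolute
    value and the most recent beat-onset time."""

    delta: float
    held: float | None = None
    t_b: float = 0.0


# ---------------------------------------------------------------------------
# numba cores
# ---------------------------------------------------------------------------

@njit(cache=True)
def _afferent_freq(p_tilde, p_n, f_min, f_max, k_a):
    x = (p_tilde - p_n) / k_a
    if x > 0.0:
        ex = math.exp(-x)
        return (f_min * ex + f_max) / (ex + 1.0)
    ex = math.exp(x)
    return (f_min + f_max * ex) / (1.0 + ex)


@njit(cache=True)
def _sympathetic_freq(f_cs, f_es_inf, f_es_0, k_es):
    return f_es_inf + (f_es_0 - f_es_inf) * math.exp(-k_es * f_cs)


@njit(cache=True)
def _vagal_freq(f_cs, f_ev_0, f_ev_inf, f_cs0, k_ev):
    x = (f_cs - f_cs0) / k_ev
    if x > 0.0:
        ex = math.exp(-x)
        return (f_ev_0 * ex + f_ev_inf) / (ex + 1.0)
    ex = math.exp(x)
    return (f_ev_0 + f_ev_inf * ex) / (1.0 + ex)


@njit(cache=True)
def _sympathetic_static(f_es_delayed, g, f_es_min):
    if f_es_delayed < f_es_min:
        return 0.0
    return g * math.log(f_es_delayed - f_es_min + 1.0)


# ---------------------------------------------------------------------------
# python API
# ---------------------------------------------------------------------------

def afferent_rate(p_art: float, dpart_dt: float, p_tilde: float,
                  tau_p: float, tau_z: float) -> float:
    """dP_tilde/dt of the afferent pole-zero filter:
    ``tau_p dP~/dt = P_art + tau_z dP_art/dt - P~``."""
    if tau_p <= 0.0:
        raise ValueError("tau_p must be positive")
    return (p_art + tau_z * dpart_dt - p_tilde) / tau_p


def afferent_frequency(p_tilde: float, baro: BaroParams) -> float:
    """Afferent carotid-sinus spiking frequency (spikes/s), a sigmoid in the
    control pressure bounded by (f_min, f_max) and centred at the set-point."""
    return float(_afferent_freq(p_tilde, baro.p_n, baro.f_min, baro.f_max,
                                baro.k_a))


def sympathetic_frequency(f_cs: float, baro: BaroParams) -> float:
    """Sympathetic efferent frequency: exponential decay from f_es,0 at zero
    afferent drive toward f_es,inf."""
    return float(_sympathetic_freq(f_cs, baro.f_es_inf, baro.f_es_0, baro.k_es))


def vagal_frequency(f_cs: float, baro: BaroParams) -> float:
    """Vagal efferent frequency: increasing sigmoid from f_ev,0 to f_ev,inf
    centred at f_cs,0."""
    return float(_vagal_freq(f_cs, baro.f_ev_0, baro.f_ev_inf, baro.f_cs0,
                             baro.k_ev))


def sympathetic_static(f_es_delayed: float, spec: EffectorSpec,
                       f_es_min: float) -> float:
    """Sympathetic static characteristic G ln(f_es(t-D) - f_es,min + 1),
    zero (continuously) below the f_es,min threshold."""
    return float(_sympathetic_static(f_es_delayed, spec.g, f_es_min))


def vagal_static(f_ev_delayed: float, spec: EffectorSpec) -> float:
    """Vagal static characteristic, linear in the delayed vagal frequency."""
    return spec.g * f_ev_delayed


def effector_rate(delta: float, sigma: float, tau_theta: float) -> float:
    """First-order relaxation of the effector deviation toward its static
    characteristic: d(Delta theta)/dt = (sigma - Delta theta)/tau_theta."""
    if tau_theta <= 0.0:
        raise ValueError("tau_theta must be positive")
    return (sigma - delta) / tau_theta


def beat_promotion_rate(held: float, delta: float, theta_0: float, t: float,
                        t_b: float, sigma_width: float,
                        area: float = PROMOTION_AREA) -> float:
    """Rate of the beat-held effector state.

    A normalised-Gaussian bump centred at the beat onset ``t_b`` relaxes the
    held value toward theta_0 + Delta theta; integrating across the bump
    leaves ``held = theta_0 + delta`` up to a residual factor exp(-area).
    Away from the beat (|t - t_b| >> sigma_width) the rate is numerically
    zero, so the held value is constant within a beat.
    """
    if sigma_width <= 0.0:
        raise ValueError("sigma_width must be positive")
    z = (t - t_b) / sigma_width
    bump = math.exp(-0.5 * z * z) / (sigma_width * math.sqrt(2.0 * math.pi))
    return area * bump * (theta_0 + delta - held)


def unstressed_volume_coupling(p_art: float, p_node: float, e_a: float,
                               de_a: float, c_ven: float, r_sys: float,
                               ddelta_vun_dt: float, i_tv: float) -> float:
    """Combined stressed-venous/right-atrial dynamics under unstressed-volume
    regulation::

        dP_RA/dt = E_RA/(1 + C_ven E_RA) ((P_A - P_RA)/R_sys
                                          + dDelta/dt - i_TV)
                   + E_RA'/(E_RA (1 + C_ven E_RA)) P_RA

    ``ddelta_vun_dt`` is the rate (ml/s) at which regulation injects volume
    into the stressed pool; with the venous unstressed volume written as
    V_un,init + Delta theta_Vun this is -d(Delta theta_Vun)/dt, so falling
    pressure (sympathetic drive, negative gain) shrinks the unstressed pool
    and adds stressed volume.
    """
    denom = 1.0 + c_ven * e_a
    if denom <= 0.0:
        raise ValueError("non-physical: 1 + C_ven*E_RA <= 0")
    return (e_a / denom * ((p_art - p_node) / r_sys + ddelta_vun_dt - i_tv)
            + de_a / (e_a * denom) * p_node)
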