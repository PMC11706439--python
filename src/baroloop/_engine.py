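"""Compiled production integrator.

Fixed-step classical RK4 on the volume-eliminated pressure states, with

* cubic-Hermite interpolation of the stored afferent-pressure history for the
  delayed efferent pathways (locally 4th-order accurate, matching the step
  order; history before t=0 is the constant initial state),
* beat events at analytically known times (the held heart period is constant
  within a beat, so the next onset is t_b + tau_held), where the beat-to-beat
  effectors are promoted to base + deviation — the exact limit of the
  narrow-Gaussian promotion bump,
* per-cycle extrema tracking for output extraction, and
* a flat parameter-array layout shared by all four model variants so that
  sensitivity drivers can evaluate thousands of perturbed parameter sets
  without touching python objects.

The python-facing API lives in :mod:`baroloop.simulator`; this module is
internal.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .hemodynamics import _elastance_pair, _valve
from .baroreflex import _afferent_freq, _sympathetic_freq, _vagal_freq, \
    _sympathetic_static
from . import parameters as pm

# --- parameter array layout (length NP) ------------------------------------
I_TAU0, I_MCFP = 0, 1
I_ELVMIN, I_ELVMAX, I_ERVMIN, I_ERVMAX = 2, 3, 4, 5
I_ELAMIN, I_ELAMAX, I_ERAMIN, I_ERAMAX = 6, 7, 8, 9
I_VI, I_VS1, I_VS2, I_AI, I_AS1, I_AS2 = 10, 11, 12, 13, 14, 15
I_RMV, I_RAV, I_RTV, I_RPV = 16, 17, 18, 19
I_CART, I_RSYS, I_CVEN, I_CPULA, I_RPUL, I_CPULV, I_VUNINIT = \
    20, 21, 22, 23, 24, 25, 26
I_PN, I_FMIN, I_FMAX, I_KA, I_FCS0, I_TAUP, I_TAUZ = 27, 28, 29, 30, 31, 32, 33
I_FESINF, I_FES0, I_FESMIN, I_KES, I_FEV0, I_FEVINF, I_KEV = \
    34, 35, 36, 37, 38, 39, 40
I_GELV, I_TELV, I_DELV = 41, 42, 43
I_GERV, I_TERV, I_DERV = 44, 45, 46
I_GR, I_TR, I_DR = 47, 48, 49
I_GVUN, I_TVUN, I_DVUN = 50, 51, 52
I_GTS, I_TTS, I_DTS = 53, 54, 55
I_GTV, I_TTV, I_DTV = 56, 57, 58
I_VLV0 = 59  # initial LV volume (ml); sets the conserved total volume
NP = 60

# --- state layout (length NS) ----------------------------------------------
S_PLV, S_PART, S_PVEN, S_PRV, S_PPULA, S_PPULV = 0, 1, 2, 3, 4, 5
S_PT = 6          # filtered afferent pressure
S_DELV, S_DERV, S_DR, S_DVUN, S_DTS, S_DTV = 7, 8, 9, 10, 11, 12
NS = 13

#: engine index of every named scalar that can appear in a free-parameter list
ENGINE_INDEX = {
    "tau_hr0": I_TAU0, "mcfp": I_MCFP,
    "e_lvmin": I_ELVMIN, "e_lvmax": I_ELVMAX,
    "e_rvmin": I_ERVMIN, "e_rvmax": I_ERVMAX,
    "e_lamin": I_ELAMIN, "e_lamax": I_ELAMAX,
    "e_ramin": I_ERAMIN, "e_ramax": I_ERAMAX,
    "tau_initv": I_VI, "tau_s1v": I_VS1, "tau_s2v": I_VS2,
    "tau_inita": I_AI, "tau_s1a": I_AS1, "tau_s2a": I_AS2,
    "r_mv": I_RMV, "r_av": I_RAV, "r_tv": I_RTV, "r_pv": I_RPV,
    "c_art": I_CART, "r_sys": I_RSYS, "c_ven": I_CVEN,
    "c_pula": I_CPULA, "r_pul": I_RPUL, "c_pulv": I_CPULV,
    "v_unv_init": I_VUNINIT,
    "p_n": I_PN, "f_min": I_FMIN, "f_max": I_FMAX, "k_a": I_KA,
    "f_cs0": I_FCS0, "tau_p": I_TAUP, "tau_z": I_TAUZ,
    "f_es_inf": I_FESINF, "f_es_0": I_FES0, "f_es_min": I_FESMIN,
    "k_es": I_KES, "f_ev_0": I_FEV0, "f_ev_inf": I_FEVINF, "k_ev": I_KEV,
    "g_emax_lv": I_GELV, "tau_emax_lv": I_TELV, "d_emax_lv": I_DELV,
    "g_emax_rv": I_GERV, "tau_emax_rv": I_TERV, "d_emax_rv": I_DERV,
    "g_rsys": I_GR, "tau_rsys": I_TR, "d_rsys": I_DR,
    "g_vunv": I_GVUN, "tau_vunv": I_TVUN, "d_vunv": I_DVUN,
    "g_tau_s": I_GTS, "tau_tau_s": I_TTS, "d_tau_s": I_DTS,
    "g_tau_v": I_GTV, "tau_tau_v": I_TTV, "d_tau_v": I_DTV,
}


def pack(params: pm.ModelParameters) -> np.ndarray:
    """Flat engine parameter array for a validated parameter set."""
    p = np.zeros(NP)
    p[I_TAU0] = params.tau_hr0
    p[I_MCFP] = params.mcfp
    lv = params.chambers["lv"]
    p[I_ELVMIN], p[I_ELVMAX] = lv.e_min, lv.e_max
    p[I_VI], p[I_VS1], p[I_VS2] = (lv.tau_init_frac, lv.tau_s1_frac,
                                   lv.tau_s2_frac)
    c = params.circulation
    p[I_RMV], p[I_RAV] = c.r_mv, c.r_av
    p[I_CART], p[I_RSYS], p[I_CVEN] = c.c_art, c.r_sys, c.c_ven
    if params.variant == "4ch":
        rv, la, ra = (params.chambers[k] for k in ("rv", "la", "ra"))
        p[I_ERVMIN], p[I_ERVMAX] = rv.e_min, rv.e_max
        p[I_ELAMIN], p[I_ELAMAX] = la.e_min, la.e_max
        p[I_ERAMIN], p[I_ERAMAX] = ra.e_min, ra.e_max
        p[I_AI], p[I_AS1], p[I_AS2] = (ra.tau_init_frac, ra.tau_s1_frac,
                                       ra.tau_s2_frac)
        p[I_RTV], p[I_RPV] = c.r_tv, c.r_pv
        p[I_CPULA], p[I_RPUL], p[I_CPULV] = c.c_pula, c.r_pul, c.c_pulv
        p[I_VUNINIT] = c.v_unv_init
    else:
        # unused slots must stay away from zero divisors
        p[I_ERVMIN] = p[I_ERVMAX] = 1.0
        p[I_ELAMIN] = p[I_ELAMAX] = p[I_ERAMIN] = p[I_ERAMAX] = 1.0
        p[I_AS1], p[I_AS2] = 0.5, 1.0
        p[I_RTV] = p[I_RPV] = p[I_CPULA] = p[I_RPUL] = p[I_CPULV] = 1.0
    p[I_TELV] = p[I_TERV] = p[I_TR] = p[I_TVUN] = p[I_TTS] = p[I_TTV] = 1.0
    p[I_TAUP] = p[I_KA] = p[I_KES] = p[I_KEV] = 1.0
    if params.v_lv_init is not None:
        p[I_VLV0] = params.v_lv_init
    elif params.variant == "1ch":
        p[I_VLV0] = pm.DEFAULT_V_LV_INIT_1CH
    else:
        p[I_VLV0] = params.mcfp / params.chambers["lv"].e_min
    if params.regulated:
        b = params.baro
        p[I_PN], p[I_FMIN], p[I_FMAX], p[I_KA] = b.p_n, b.f_min, b.f_max, b.k_a
        p[I_FCS0], p[I_TAUP], p[I_TAUZ] = b.f_cs0, b.tau_p, b.tau_z
        p[I_FESINF], p[I_FES0], p[I_FESMIN] = b.f_es_inf, b.f_es_0, b.f_es_min
        p[I_KES], p[I_FEV0], p[I_FEVINF], p[I_KEV] = (b.k_es, b.f_ev_0,
                                                      b.f_ev_inf, b.k_ev)
        for name, (target, arc) in (
                (("g_emax_lv", "tau_emax_lv", "d_emax_lv"), ("e_lvmax", None)),
                (("g_rsys", "tau_rsys", "d_rsys"), ("r_sys", None)),
                (("g_tau_s", "tau_tau_s", "d_tau_s"), ("tau_hr", "sympathetic")),
                (("g_tau_v", "tau_tau_v", "d_tau_v"), ("tau_hr", "vagal"))):
            spec = b.effector(target, arc)
            p[ENGINE_INDEX[name[0]]] = spec.g
            p[ENGINE_INDEX[name[1]]] = spec.tau
            p[ENGINE_INDEX[name[2]]] = spec.d
        if params.variant == "4ch":
            for name, target in ((("g_emax_rv", "tau_emax_rv", "d_emax_rv"),
                                  "e_rvmax"),
                                 (("g_vunv", "tau_vunv", "d_vunv"), "v_unv")):
                spec = b.effector(target)
                p[ENGINE_INDEX[name[0]]] = spec.g
                p[ENGINE_INDEX[name[1]]] = spec.tau
                p[ENGINE_INDEX[name[2]]] = spec.d
    return p


@njit(cache=True)
def _hist_eval(td, ht, hp, hdp, nh, hints, ch):
    """Cubic Hermite evaluation of the stored scalar history at time td.

    ``hints[ch]`` caches the last bracketing index of delay channel ``ch``;
    the delayed times advance monotonically during integration, so the
    incremental scan is O(1) per call.
    """
    if td <= ht[0]:
        return hp[0]
    if td >= ht[nh - 1]:
        return hp[nh - 1]
    lo = hints[ch]
    if lo > nh - 2:
        lo = nh - 2
    if lo < 0:
        lo = 0
    while lo < nh - 2 and ht[lo + 1] <= td:
        lo += 1
    while lo > 0 and ht[lo] > td:
        lo -= 1
    hints[ch] = lo
    hi = lo + 1
    h = ht[hi] - ht[lo]
    if h <= 0.0:
        return hp[lo]
    s = (td - ht[lo]) / h
    s2 = s * s
    s3 = s2 * s
    return ((2.0 * s3 - 3.0 * s2 + 1.0) * hp[lo]
            + (s3 - 2.0 * s2 + s) * h * hdp[lo]
            + (-2.0 * s3 + 3.0 * s2) * hp[hi]
            + (s3 - s2) * h * hdp[hi])


@njit(cache=True)
def _delayed_fes(t, d, p, ht, hp, hdp, nh, hints, ch):
    ptd = _hist_eval(t - d, ht, hp, hdp, nh, hints, ch)
    fcs = _afferent_freq(ptd, p[I_PN], p[I_FMIN], p[I_FMAX], p[I_KA])
    return _sympathetic_freq(fcs, p[I_FESINF], p[I_FES0], p[I_KES])


@njit(cache=True)
def _rhs(t, y, p, four, reg, tb, tau_held, elv_held, erv_held,
         ht, hp, hdp, nh, hints, dy):
    """Right-hand side of the closed-loop system; fills dy."""
    vun_inj = 0.0
    if reg:
        fes = _delayed_fes(t, p[I_DELV], p, ht, hp, hdp, nh, hints, 0)
        sig = _sympathetic_static(fes, p[I_GELV], p[I_FESMIN])
        dy[S_DELV] = (sig - y[S_DELV]) / p[I_TELV]

        fes = _delayed_fes(t, p[I_DR], p, ht, hp, hdp, nh, hints, 1)
        sig = _sympathetic_static(fes, p[I_GR], p[I_FESMIN])
        dy[S_DR] = (sig - y[S_DR]) / p[I_TR]

        fes = _delayed_fes(t, p[I_DTS], p, ht, hp, hdp, nh, hints, 2)
        sig = _sympathetic_static(fes, p[I_GTS], p[I_FESMIN])
        dy[S_DTS] = (sig - y[S_DTS]) / p[I_TTS]

        ptd = _hist_eval(t - p[I_DTV], ht, hp, hdp, nh, hints, 3)
        fcs = _afferent_freq(ptd, p[I_PN], p[I_FMIN], p[I_FMAX], p[I_KA])
        fev = _vagal_freq(fcs, p[I_FEV0], p[I_FEVINF], p[I_FCS0], p[I_KEV])
        dy[S_DTV] = (p[I_GTV] * fev - y[S_DTV]) / p[I_TTV]

        if four:
            fes = _delayed_fes(t, p[I_DERV], p, ht, hp, hdp, nh, hints, 4)
            sig = _sympathetic_static(fes, p[I_GERV], p[I_FESMIN])
            dy[S_DERV] = (sig - y[S_DERV]) / p[I_TERV]

            fes = _delayed_fes(t, p[I_DVUN], p, ht, hp, hdp, nh, hints, 5)
            sig = _sympathetic_static(fes, p[I_GVUN], p[I_FESMIN])
            dy[S_DVUN] = (sig - y[S_DVUN]) / p[I_TVUN]
            # unstressed volume V_un = V_init + Delta; shrinking V_un
            # injects volume into the stressed pool
            vun_inj = -dy[S_DVUN]
        else:
            dy[S_DERV] = 0.0
            dy[S_DVUN] = 0.0
    else:
        dy[S_DELV] = dy[S_DERV] = dy[S_DR] = 0.0
        dy[S_DVUN] = dy[S_DTS] = dy[S_DTV] = 0.0

    tc = t - tb
    e_lvmax = elv_held if reg else p[I_ELVMAX]
    e_lv, de_lv = _elastance_pair(tc, tau_held, p[I_ELVMIN], e_lvmax,
                                  p[I_VI], p[I_VS1], p[I_VS2])
    r_sys = p[I_RSYS] + (y[S_DR] if reg else 0.0)

    if not four:
        q_mv = _valve(y[S_PVEN], y[S_PLV], p[I_RMV])
        q_av = _valve(y[S_PLV], y[S_PART], p[I_RAV])
        q_sys = (y[S_PART] - y[S_PVEN]) / r_sys
        dy[S_PLV] = de_lv / e_lv * y[S_PLV] + e_lv * (q_mv - q_av)
        dy[S_PART] = (q_av - q_sys) / p[I_CART]
        dy[S_PVEN] = (q_sys - q_mv) / p[I_CVEN]
        dy[S_PRV] = dy[S_PPULA] = dy[S_PPULV] = 0.0
    else:
        e_rvmax = erv_held if reg else p[I_ERVMAX]
        e_rv, de_rv = _elastance_pair(tc, tau_held, p[I_ERVMIN], e_rvmax,
                                      p[I_VI], p[I_VS1], p[I_VS2])
        e_la, de_la = _elastance_pair(tc, tau_held, p[I_ELAMIN], p[I_ELAMAX],
                                      p[I_AI], p[I_AS1], p[I_AS2])
        e_ra, de_ra = _elastance_pair(tc, tau_held, p[I_ERAMIN], p[I_ERAMAX],
                                      p[I_AI], p[I_AS1], p[I_AS2])
        q_mv = _valve(y[S_PPULV], y[S_PLV], p[I_RMV])
        q_av = _valve(y[S_PLV], y[S_PART], p[I_RAV])
        q_sys = (y[S_PART] - y[S_PVEN]) / r_sys
        q_tv = _valve(y[S_PVEN], y[S_PRV], p[I_RTV])
        q_pv = _valve(y[S_PRV], y[S_PPULA], p[I_RPV])
        q_pul = (y[S_PPULA] - y[S_PPULV]) / p[I_RPUL]
        dy[S_PLV] = de_lv / e_lv * y[S_PLV] + e_lv * (q_mv - q_av)
        dy[S_PART] = (q_av - q_sys) / p[I_CART]
        den_ra = 1.0 + p[I_CVEN] * e_ra
        dy[S_PVEN] = (e_ra / den_ra * (q_sys + vun_inj - q_tv)
                      + de_ra / (e_ra * den_ra) * y[S_PVEN])
        dy[S_PRV] = de_rv / e_rv * y[S_PRV] + e_rv * (q_tv - q_pv)
        dy[S_PPULA] = (q_pv - q_pul) / p[I_CPULA]
        den_la = 1.0 + p[I_CPULV] * e_la
        dy[S_PPULV] = (e_la / den_la * (q_pul - q_mv)
                       + de_la / (e_la * den_la) * y[S_PPULV])

    if reg:
        dy[S_PT] = (y[S_PART] + p[I_TAUZ] * dy[S_PART] - y[S_PT]) / p[I_TAUP]
    else:
        dy[S_PT] = 0.0


@njit(cache=True)
def _stressed_total(y, p, four, tc, tau, elv_held, erv_held, reg):
    e_lvmax = elv_held if reg else p[I_ELVMAX]
    e_lv, _ = _elastance_pair(tc, tau, p[I_ELVMIN], e_lvmax,
                              p[I_VI], p[I_VS1], p[I_VS2])
    tot = y[S_PLV] / e_lv + p[I_CART] * y[S_PART]
    if not four:
        return tot + p[I_CVEN] * y[S_PVEN]
    e_rvmax = erv_held if reg else p[I_ERVMAX]
    e_rv, _ = _elastance_pair(tc, tau, p[I_ERVMIN], e_rvmax,
                              p[I_VI], p[I_VS1], p[I_VS2])
    e_la, _ = _elastance_pair(tc, tau, p[I_ELAMIN], p[I_ELAMAX],
                              p[I_AI], p[I_AS1], p[I_AS2])
    e_ra, _ = _elastance_pair(tc, tau, p[I_ERAMIN], p[I_ERAMAX],
                              p[I_AI], p[I_AS1], p[I_AS2])
    return (tot + y[S_PRV] / e_rv
            + y[S_PVEN] / e_ra + p[I_CVEN] * y[S_PVEN]
            + y[S_PPULV] / e_la + p[I_CPULV] * y[S_PPULV]
            + p[I_CPULA] * y[S_PPULA])


NAUX = 8  # tau_held, elv_held, erv_held, r_sys, delta_vun, v_lv, v_rv, volume


@njit(cache=True)
def _integrate(p, four, reg, t_end, dt, sample_dt):
    """Integrate one model; returns sampled trajectory, beat bookkeeping and
    last-complete-cycle extrema.

    Returns (ts, Y, AUX, beat_t, beat_tau, last_lo, last_hi, last_cycle_tau,
    n_cycles, ok).
    """
    n_press = 6 if four else 3
    nact = NS if reg else n_press  # states actually integrated
    y = np.zeros(NS)
    mcfp = p[I_MCFP]
    for i in range(n_press):
        y[i] = mcfp
    # LV volume is a separate structural constant; P_LV(0) = E(0) V_LV(0)
    y[S_PLV] = p[I_ELVMIN] * p[I_VLV0]
    y[S_PT] = mcfp
    tau_held = p[I_TAU0]
    elv_held = p[I_ELVMAX]
    erv_held = p[I_ERVMAX]

    cap_hist = int(t_end / dt) + int(t_end / sample_dt) + int(t_end / 0.1) + 32
    ht = np.empty(cap_hist)
    hp = np.empty(cap_hist)
    hdp = np.empty(cap_hist)
    nh = 1

    hints = np.zeros(6, dtype=np.int64)
    k1 = np.zeros(NS)
    k2 = np.zeros(NS)
    k3 = np.zeros(NS)
    k4 = np.zeros(NS)
    yt = np.zeros(NS)

    ht[0] = 0.0
    hp[0] = y[S_PT]
    hdp[0] = 0.0
    _rhs(0.0, y, p, four, reg, 0.0, tau_held, elv_held, erv_held,
         ht, hp, hdp, 1, hints, k1)
    hdp[0] = k1[S_PT]

    n_samp = int(math.floor(t_end / sample_dt + 1e-9)) + 1
    ts = np.empty(n_samp)
    Y = np.empty((n_samp, NS))
    AUX = np.empty((n_samp, NAUX))

    cap_beat = int(t_end / 0.1) + 4
    beat_t = np.empty(cap_beat)
    beat_tau = np.empty(cap_beat)

    cur_lo = np.empty(7)
    cur_hi = np.empty(7)
    last_lo = np.empty(7)
    last_hi = np.empty(7)
    for i in range(7):
        v = y[i] if i < 6 else y[S_PLV] / p[I_ELVMIN]
        cur_lo[i] = v
        cur_hi[i] = v
        last_lo[i] = v
        last_hi[i] = v
    last_cycle_tau = 0.0
    n_cycles = 0

    # record sample 0
    ts[0] = 0.0
    Y[0] = y
    AUX[0, 0] = tau_held
    AUX[0, 1] = elv_held
    AUX[0, 2] = erv_held
    AUX[0, 3] = p[I_RSYS]
    AUX[0, 4] = 0.0
    AUX[0, 5] = y[S_PLV] / p[I_ELVMIN]
    AUX[0, 6] = (y[S_PRV] / p[I_ERVMIN]) if four else 0.0
    AUX[0, 7] = _stressed_total(y, p, four, 0.0, tau_held, elv_held,
                                erv_held, reg)
    isamp = 1

    beat_t[0] = 0.0
    beat_tau[0] = tau_held
    nbeat = 1
    tb = 0.0
    next_beat = tau_held
    ok = True
    # conserved stressed volume at t=0 (projection target; the regulated
    # four-chamber loop exchanges volume with the unstressed pool)
    vol0 = _stressed_total(y, p, four, 0.0, tau_held, elv_held, erv_held, reg)

    t = 0.0
    while t < t_end - 1e-9:
        tt = t + dt
        if tt > next_beat:
            tt = next_beat
        ns_t = sample_dt * isamp
        if isamp < n_samp and tt > ns_t:
            tt = ns_t
        if tt > t_end:
            tt = t_end
        h = tt - t
        if h < 1e-14:
            h = 1e-14
            tt = t + h

        for i in range(nact):
            yt[i] = y[i] + 0.5 * h * k1[i]
        _rhs(t + 0.5 * h, yt, p, four, reg, tb, tau_held, elv_held, erv_held,
             ht, hp, hdp, nh, hints, k2)
        for i in range(nact):
            yt[i] = y[i] + 0.5 * h * k2[i]
        _rhs(t + 0.5 * h, yt, p, four, reg, tb, tau_held, elv_held, erv_held,
             ht, hp, hdp, nh, hints, k3)
        for i in range(nact):
            yt[i] = y[i] + h * k3[i]
        _rhs(t + h, yt, p, four, reg, tb, tau_held, elv_held, erv_held,
             ht, hp, hdp, nh, hints, k4)
        for i in range(nact):
            y[i] = y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        t = tt

        # FSAL-style evaluation at the new point (reused as next k1 and as
        # the history derivative)
        _rhs(t, y, p, four, reg, tb, tau_held, elv_held, erv_held,
             ht, hp, hdp, nh, hints, k1)
        if reg and nh < cap_hist:
            ht[nh] = t
            hp[nh] = y[S_PT]
            hdp[nh] = k1[S_PT]
            nh += 1

        tc = t - tb
        e_lvmax = elv_held if reg else p[I_ELVMAX]
        e_lv, _ = _elastance_pair(tc, tau_held, p[I_ELVMIN], e_lvmax,
                                  p[I_VI], p[I_VS1], p[I_VS2])
        v_lv = y[S_PLV] / e_lv
        for i in range(n_press):
            if y[i] < cur_lo[i]:
                cur_lo[i] = y[i]
            if y[i] > cur_hi[i]:
                cur_hi[i] = y[i]
        if v_lv < cur_lo[6]:
            cur_lo[6] = v_lv
        if v_lv > cur_hi[6]:
            cur_hi[6] = v_lv

        if t >= next_beat - 1e-12:
            finite = True
            for i in range(nact):
                if not np.isfinite(y[i]):
                    finite = False
            if not finite:
                ok = False
                break
            for i in range(7):
                last_lo[i] = cur_lo[i]
                last_hi[i] = cur_hi[i]
                cur_lo[i] = y[i] if i < 6 else v_lv
                cur_hi[i] = cur_lo[i]
            last_cycle_tau = t - tb
            n_cycles += 1
            # volume-conservation projection: all stressed volumes are
            # linear in the pressures, so a uniform pressure rescaling
            # restores the conserved total exactly and removes the secular
            # O(h^4)-per-step drift of the eliminated ventricular states
            target = vol0 - (y[S_DVUN] if (reg and four) else 0.0)
            cur = _stressed_total(y, p, four, t - tb, tau_held, elv_held,
                                  erv_held, reg)
            if cur > 0.0 and target > 0.0:
                r = target / cur
                if 0.5 < r < 2.0:
                    for i in range(n_press):
                        y[i] *= r
            if reg:
                tau_new = p[I_TAU0] + y[S_DTS] + y[S_DTV]
                if tau_new < 0.1:
                    tau_new = 0.1
                tau_held = tau_new
                elv_held = p[I_ELVMAX] + y[S_DELV]
                if elv_held < 1.05 * p[I_ELVMIN]:
                    elv_held = 1.05 * p[I_ELVMIN]
                if four:
                    erv_held = p[I_ERVMAX] + y[S_DERV]
                    if erv_held < 1.05 * p[I_ERVMIN]:
                        erv_held = 1.05 * p[I_ERVMIN]
            tb = t
            next_beat = t + tau_held
            if nbeat < cap_beat:
                beat_t[nbeat] = t
                beat_tau[nbeat] = tau_held
                nbeat += 1
            # refresh the FSAL stage: projection and promotion changed the
            # state and the held parameters
            _rhs(t, y, p, four, reg, tb, tau_held, elv_held, erv_held,
                 ht, hp, hdp, nh, hints, k1)

        if isamp < n_samp and t >= sample_dt * isamp - 1e-12:
            ts[isamp] = t
            Y[isamp] = y
            AUX[isamp, 0] = tau_held
            AUX[isamp, 1] = elv_held
            AUX[isamp, 2] = erv_held
            AUX[isamp, 3] = p[I_RSYS] + (y[S_DR] if reg else 0.0)
            AUX[isamp, 4] = y[S_DVUN]
            AUX[isamp, 5] = v_lv
            e_rvmax = erv_held if reg else p[I_ERVMAX]
            if four:
                e_rv, _ = _elastance_pair(t - tb, tau_held, p[I_ERVMIN],
                                          e_rvmax, p[I_VI], p[I_VS1], p[I_VS2])
                AUX[isamp, 6] = y[S_PRV] / e_rv
            else:
                AUX[isamp, 6] = 0.0
            AUX[isamp, 7] = _stressed_total(y, p, four, t - tb, tau_held,
                                            elv_held, erv_held, reg) \
                + (y[S_DVUN] if (reg and four) else 0.0)
            isamp += 1

    if not np.isfinite(y).all():
        ok = False
    return (ts[:isamp], Y[:isamp], AUX[:isamp], beat_t[:nbeat],
            beat_tau[:nbeat], last_lo, last_hi, last_cycle_tau, n_cycles, ok)


NOUT_1CH = 10
NOUT_4CH = 16


@njit(cache=True)
def _run_outputs(p, four, reg, t_end, dt, out):
    """One model run; fills the raw clinical output vector.

    Layout: [CO, tau_HR, V_LV max/min, P_LV max/min, P_art max/min,
    P_ven max/min, (4CH: P_RV, P_pulA, P_pulV max/min)].  Returns True on a
    finite run with at least 2 completed cycles.
    """
    res = _integrate(p, four, reg, t_end, dt, t_end)
    last_lo, last_hi, cyc_tau, n_cycles, ok = res[5], res[6], res[7], res[8], \
        res[9]
    if (not ok) or n_cycles < 2 or cyc_tau <= 0.0:
        for i in range(out.shape[0]):
            out[i] = np.nan
        return False
    out[0] = (last_hi[6] - last_lo[6]) / cyc_tau
    out[1] = cyc_tau
    out[2] = last_hi[6]
    out[3] = last_lo[6]
    out[4] = last_hi[S_PLV]
    out[5] = last_lo[S_PLV]
    out[6] = last_hi[S_PART]
    out[7] = last_lo[S_PART]
    out[8] = last_hi[S_PVEN]
    out[9] = last_lo[S_PVEN]
    if four:
        out[10] = last_hi[S_PRV]
        out[11] = last_lo[S_PRV]
        out[12] = last_hi[S_PPULA]
        out[13] = last_lo[S_PPULA]
        out[14] = last_hi[S_PPULV]
        out[15] = last_lo[S_PPULV]
    return True


@njit(cache=True)
def batch_outputs(pmat, four, reg, t_end, dt):
    """Raw output vectors for every row of a packed parameter matrix.

    Failed (non-finite) runs yield NaN rows; callers decide the imputation
    policy.
    """
    n = pmat.shape[0]
    m = NOUT_4CH if four else NOUT_1CH
    out = np.empty((n, m))
    for i in range(n):
        _run_outputs(pmat[i], four, reg, t_end, dt, out[i])
    return out
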