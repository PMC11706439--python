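"""Adaptive-tolerance reference integrator (method of steps).

An independent assembly of the closed-loop system on top of
``scipy.integrate.solve_ivp`` (RK45, dense output), used to cross-validate
the compiled fixed-step production integrator:

* the delay terms are evaluated from the dense output of previous integration
  segments, with segment lengths capped below the shortest transport delay so
  every delayed lookup falls in already-completed history (classic method of
  steps; history before t = 0 is the constant initial state);
* beat-to-beat promotion is applied at the analytically known beat onsets;
* no volume-conservation projection is applied — the adaptive error control
  keeps the drift within tolerance over the short horizons this path is used
  for.

This path is one to two orders of magnitude slower than the production
engine and is intended for validation, not for sensitivity sweeps.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import baroreflex as br
from .hemodynamics import _elastance_pair, _valve
from .parameters import ModelParameters, DEFAULT_V_LV_INIT_1CH
from .simulator import SimulationConfig, Trajectory

__all__ = ["simulate_reference"]


class _History:
    """Piecewise dense solution of the afferent pressure state."""

    def __init__(self, y0: float):
        self.y0 = y0
        self.segments: list = []   # (t0, t1, OdeSolution)

    def append(self, t0: float, t1: float, sol) -> None:
        self.segments.append((t0, t1, sol))

    def p_tilde(self, t: float) -> float:
        if t <= 0.0 or not self.segments:
            return self.y0
        # segments are contiguous and ordered; scan from the end
        for t0, t1, sol in reversed(self.segments):
            if t >= t0 - 1e-12:
                return float(sol(min(t, t1))[6])
        return self.y0


def simulate_reference(params: ModelParameters,
                       config: SimulationConfig | None = None) -> Trajectory:
    """Integrate with adaptive RK45 at ``config.abs_tol``/``rel_tol``."""
    config = config or SimulationConfig()
    params.validate()
    four = params.variant == "4ch"
    reg = params.regulated
    c = params.circulation
    lv = params.chambers["lv"]
    if four:
        rv, la, ra = (params.chambers[k] for k in ("rv", "la", "ra"))
    baro = params.baro
    if reg:
        e_elv = baro.effector("e_lvmax")
        e_r = baro.effector("r_sys")
        e_ts = baro.effector("tau_hr", "sympathetic")
        e_tv = baro.effector("tau_hr", "vagal")
        e_erv = baro.effector("e_rvmax") if four else None
        e_vun = baro.effector("v_unv") if four else None
        delays = [e.d for e in baro.effectors]
        min_delay = max(min(delays), 1e-3)
    else:
        min_delay = np.inf

    t_end = config.resolve_t_end(params.variant)
    n_press = 6 if four else 3
    y0 = np.zeros(13)
    y0[:n_press] = params.mcfp
    v_lv0 = params.v_lv_init if params.v_lv_init is not None else (
        DEFAULT_V_LV_INIT_1CH if params.variant == "1ch"
        else params.mcfp / lv.e_min)
    y0[0] = lv.e_min * v_lv0
    y0[6] = params.mcfp
    hist = _History(y0[6])

    held = {"tau": params.tau_hr0, "elv": lv.e_max,
            "erv": rv.e_max if four else 1.0}
    tb = [0.0]

    def delayed_sigma_s(t: float, spec) -> float:
        f_cs = br.afferent_frequency(hist.p_tilde(t - spec.d), baro)
        f_es = br.sympathetic_frequency(f_cs, baro)
        return br.sympathetic_static(f_es, spec, baro.f_es_min)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(13)
        vun_inj = 0.0
        if reg:
            dy[7] = br.effector_rate(y[7], delayed_sigma_s(t, e_elv), e_elv.tau)
            dy[9] = br.effector_rate(y[9], delayed_sigma_s(t, e_r), e_r.tau)
            dy[11] = br.effector_rate(y[11], delayed_sigma_s(t, e_ts), e_ts.tau)
            f_cs = br.afferent_frequency(hist.p_tilde(t - e_tv.d), baro)
            f_ev = br.vagal_frequency(f_cs, baro)
            dy[12] = br.effector_rate(y[12], br.vagal_static(f_ev, e_tv),
                                      e_tv.tau)
            if four:
                dy[8] = br.effector_rate(y[8], delayed_sigma_s(t, e_erv),
                                         e_erv.tau)
                dy[10] = br.effector_rate(y[10], delayed_sigma_s(t, e_vun),
                                          e_vun.tau)
                vun_inj = -dy[10]
        tau = held["tau"]
        tc = t - tb[0]
        e_lvmax = held["elv"] if reg else lv.e_max
        e_lv, de_lv = _elastance_pair(tc, tau, lv.e_min, e_lvmax,
                                      lv.tau_init_frac, lv.tau_s1_frac,
                                      lv.tau_s2_frac)
        r_sys = c.r_sys + (y[9] if reg else 0.0)
        if not four:
            q_mv = _valve(y[2], y[0], c.r_mv)
            q_av = _valve(y[0], y[1], c.r_av)
            q_sys = (y[1] - y[2]) / r_sys
            dy[0] = de_lv / e_lv * y[0] + e_lv * (q_mv - q_av)
            dy[1] = (q_av - q_sys) / c.c_art
            dy[2] = (q_sys - q_mv) / c.c_ven
        else:
            e_rvmax = held["erv"] if reg else rv.e_max
            e_rv, de_rv = _elastance_pair(tc, tau, rv.e_min, e_rvmax,
                                          rv.tau_init_frac, rv.tau_s1_frac,
                                          rv.tau_s2_frac)
            e_la, de_la = _elastance_pair(tc, tau, la.e_min, la.e_max,
                                          la.tau_init_frac, la.tau_s1_frac,
                                          la.tau_s2_frac)
            e_ra, de_ra = _elastance_pair(tc, tau, ra.e_min, ra.e_max,
                                          ra.tau_init_frac, ra.tau_s1_frac,
                                          ra.tau_s2_frac)
            q_mv = _valve(y[5], y[0], c.r_mv)
            q_av = _valve(y[0], y[1], c.r_av)
            q_sys = (y[1] - y[2]) / r_sys
            q_tv = _valve(y[2], y[3], c.r_tv)
            q_pv = _valve(y[3], y[4], c.r_pv)
            q_pul = (y[4] - y[5]) / c.r_pul
            dy[0] = de_lv / e_lv * y[0] + e_lv * (q_mv - q_av)
            dy[1] = (q_av - q_sys) / c.c_art
            dy[2] = br.unstressed_volume_coupling(
                y[1], y[2], e_ra, de_ra, c.c_ven, r_sys, vun_inj, q_tv)
            dy[3] = de_rv / e_rv * y[3] + e_rv * (q_tv - q_pv)
            dy[4] = (q_pv - q_pul) / c.c_pula
            den = 1.0 + c.c_pulv * e_la
            dy[5] = (e_la / den * (q_pul - q_mv)
                     + de_la / (e_la * den) * y[5])
        if reg:
            dy[6] = br.afferent_rate(y[1], dy[1], y[6], baro.tau_p, baro.tau_z)
        return dy

    sample_times = np.arange(0.0, t_end + config.sample_dt / 2,
                             config.sample_dt)
    samples = np.empty((sample_times.size, 13))
    aux = np.zeros((sample_times.size, 8))
    samples[0] = y0
    next_sample = 1
    beat_onsets = [0.0]
    beat_tau = [held["tau"]]
    beat_elv = [held["elv"]]

    seg_cap = 0.9 * min_delay if np.isfinite(min_delay) else np.inf
    t = 0.0
    y = y0.copy()
    while t < t_end - 1e-9:
        next_beat = tb[0] + held["tau"]
        seg_end = min(t + seg_cap, next_beat, t_end)
        sol = solve_ivp(rhs, (t, seg_end), y, method="RK45",
                        rtol=config.rel_tol, atol=config.abs_tol,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"reference integration failed at t={t:.3f}: "
                               f"{sol.message}")
        hist.append(t, seg_end, sol.sol)
        while (next_sample < sample_times.size
               and sample_times[next_sample] <= seg_end + 1e-12):
            samples[next_sample] = sol.sol(
                min(sample_times[next_sample], seg_end))
            next_sample += 1
        y = sol.y[:, -1].copy()
        t = seg_end
        if abs(t - next_beat) < 1e-12:
            if reg:
                held["tau"] = max(params.tau_hr0 + y[11] + y[12], 0.1)
                held["elv"] = max(lv.e_max + y[7], 1.05 * lv.e_min)
                if four:
                    held["erv"] = max(rv.e_max + y[8], 1.05 * rv.e_min)
            tb[0] = t
            beat_onsets.append(t)
            beat_tau.append(held["tau"])
            beat_elv.append(held["elv"])

    # aux columns for the sampled grid (held values are filled per beat)
    onsets = np.array(beat_onsets)
    taus = np.array(beat_tau)
    idx = np.clip(np.searchsorted(onsets, sample_times, side="right") - 1,
                  0, len(onsets) - 1)
    elvs = np.array(beat_elv)
    aux[:, 0] = taus[idx]
    aux[:, 1] = elvs[idx]
    aux[:, 3] = c.r_sys + (samples[:, 9] if reg else 0.0)
    aux[:, 4] = samples[:, 10]
    for i, (ti, yi) in enumerate(zip(sample_times, samples)):
        tci = min(ti - onsets[idx[i]], taus[idx[i]] * (1 - 1e-12))
        e_lv, _ = _elastance_pair(tci, taus[idx[i]], lv.e_min,
                                  elvs[idx[i]] if reg else lv.e_max,
                                  lv.tau_init_frac, lv.tau_s1_frac,
                                  lv.tau_s2_frac)
        aux[i, 5] = yi[0] / e_lv
    return Trajectory(sample_times, samples, aux, onsets, taus,
                      params.variant, params.regulated, params=params)
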