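"""Mechanical building blocks: activation, elastance, valves, assembled RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import baroloop as bl
from baroloop.hemodynamics import (ActivationClock, activation,
                                   activation_slope, elastance,
                                   elastance_slope, rhs_unregulated,
                                   total_stressed_volume, valve_flow)


class TestActivation:
    def test_anchor_points(self):
        tes, tep = 0.174, 0.261  # 0.30 tau, 0.45 tau at tau = 0.58
        assert activation(0.0, tes, tep) == pytest.approx(0.0)
        assert activation(tes, tes, tep) == pytest.approx(1.0)
        assert activation(tes / 2, tes, tep) == pytest.approx(0.5)
        assert activation(tep, tes, tep) == 0.0
        assert activation(0.5, tes, tep) == 0.0  # past end of pulse

    def test_continuity_at_breakpoints(self):
        tes, tep = 0.2, 0.35
        for x in (tes, tep):
            lo = activation(x - 1e-9, tes, tep)
            hi = activation(x + 1e-9, tes, tep)
            assert abs(hi - lo) < 1e-6

    def test_timing_order_violation_rejected(self):
        with pytest.raises(ValueError):
            activation(0.1, 0.3, 0.2)
        with pytest.raises(ValueError):
            activation_slope(0.1, 0.0, 0.2)

    @given(x=st.floats(0.0, 0.999), tes=st.floats(0.05, 0.4),
           dfall=st.floats(0.05, 0.4))
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, x, tes, dfall):
        e = activation(x, tes, tes + dfall)
        assert 0.0 <= e <= 1.0


class TestElastance:
    def test_ventricular_extremes_match_published_values(self, reg1):
        lv = reg1.chambers["lv"]
        tau = reg1.tau_hr0
        assert elastance(0.0, lv, tau) == pytest.approx(0.06)
        assert elastance(0.30 * tau, lv, tau) == pytest.approx(2.00)

    def test_atrial_wraparound_peak(self, reg4):
        """Atrial systole spans the cycle boundary: the peak at 0.96 tau
        reaches E_RAmax even though onset is 0.92 tau and end 1.0 tau."""
        ra = reg4.chambers["ra"]
        tau = reg4.tau_hr0
        assert elastance(0.96 * tau, ra, tau) == pytest.approx(0.25)
        assert elastance(0.5 * tau, ra, tau) == pytest.approx(0.15)

    @given(t=st.floats(0.0, 5.0), tau=st.floats(0.4, 1.2))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_exact_periodicity(self, t, tau, reg4):
        for ch in reg4.chambers.values():
            e = elastance(t, ch, tau)
            assert ch.e_min <= e <= ch.e_max + 1e-12
            assert elastance(t + tau, ch, tau) == pytest.approx(e, abs=1e-12)

    def test_slope_consistent_with_finite_difference(self, reg1):
        lv = reg1.chambers["lv"]
        tau, h = 0.58, 1e-7
        for t in (0.05, 0.1, 0.2, 0.3):
            fd = (elastance(t + h, lv, tau) - elastance(t - h, lv, tau)) / (2 * h)
            assert elastance_slope(t, lv, tau) == pytest.approx(fd, rel=1e-5)


class TestValveFlow:
    def test_forward_reverse_and_zero(self):
        assert valve_flow(10.0, 5.0, 0.06) == pytest.approx(83.333, abs=1e-3)
        assert valve_flow(5.0, 10.0, 0.06) == pytest.approx(-0.0833, abs=1e-4)
        assert valve_flow(7.0, 7.0, 0.033) == 0.0

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError):
            valve_flow(1.0, 0.0, 0.0)

    @given(pu=st.floats(-50, 150), pd=st.floats(-50, 150),
           dp=st.floats(0.01, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_diode_monotonicity(self, pu, pd, dp):
        r = 0.06
        assert valve_flow(pu + dp, pd, r) >= valve_flow(pu, pd, r)
        assert valve_flow(pu, pd + dp, r) <= valve_flow(pu, pd, r)


class TestRhsUnregulated:
    def test_uniform_diastolic_state_is_stationary(self, unreg1, unreg4):
        """Equal pressures with the heart relaxed (zero elastance slope)
        produce zero derivatives everywhere: no gradients, no flows."""
        for p in (unreg1, unreg4):
            n = 3 if p.variant == "1ch" else 6
            # 0.7 tau: ventricles past end-systole, atria not yet active
            clock = ActivationClock(0.7 * p.tau_hr0, p.tau_hr0)
            dy = rhs_unregulated(np.full(n, p.mcfp), p, clock)
            assert np.allclose(dy, 0.0, atol=1e-12)

    def test_systolic_onset_raises_ventricular_pressure(self, unreg1):
        """From the uniform filling state, rising elastance drives P_LV up
        and, once the aortic valve opens, ejects into the arterial node."""
        p = unreg1
        y = np.full(3, p.mcfp)
        t, dt = 0.02, 1e-3
        for _ in range(100):
            y = y + dt * rhs_unregulated(y, p, ActivationClock(t, p.tau_hr0))
            t += dt
        assert y[0] > p.mcfp          # LV pressurised
        assert y[1] > p.mcfp          # arterial node receiving ejection
        # the venous node only sees the closed-valve leak; it barely moves
        assert abs(y[2] - p.mcfp) < 0.05 * (y[0] - p.mcfp)

    def test_matches_explicit_volume_oracle(self, unreg4, rng):
        """The volume-eliminated RHS agrees with a brute-force evaluation
        that keeps the chamber volume states explicit (product rule on
        P = E(t) V) to 1e-10 on random states."""
        from baroloop.hemodynamics import _elastance_pair, _valve
        p = unreg4
        c = p.circulation
        tau = p.tau_hr0
        for _ in range(25):
            t = float(rng.uniform(0, tau))
            y = rng.uniform(2.0, 110.0, size=6)
            dy = rhs_unregulated(y, p, ActivationClock(t, tau))
            e = {}
            de = {}
            for k, ch in p.chambers.items():
                e[k], de[k] = _elastance_pair(t, tau, ch.e_min, ch.e_max,
                                              ch.tau_init_frac, ch.tau_s1_frac,
                                              ch.tau_s2_frac)
            q_mv = _valve(y[5], y[0], c.r_mv)
            q_av = _valve(y[0], y[1], c.r_av)
            q_sys = (y[1] - y[2]) / c.r_sys
            q_tv = _valve(y[2], y[3], c.r_tv)
            q_pv = _valve(y[3], y[4], c.r_pv)
            q_pul = (y[4] - y[5]) / c.r_pul
            # ventricles: V = P/E, dV = Qin - Qout, dP = E' V + E dV
            assert dy[0] == pytest.approx(
                de["lv"] * (y[0] / e["lv"]) + e["lv"] * (q_mv - q_av), abs=1e-10)
            assert dy[3] == pytest.approx(
                de["rv"] * (y[3] / e["rv"]) + e["rv"] * (q_tv - q_pv), abs=1e-10)
            # merged atrial/venous nodes: solve the DAE residual
            # C dP + d(P/E) = qin - qout for dP
            dp_ra = (q_sys - q_tv + de["ra"] * y[2] / e["ra"] ** 2) \
                / (c.c_ven + 1.0 / e["ra"])
            # equivalent closed form used by the implementation
            assert dy[2] == pytest.approx(dp_ra, rel=1e-10)
            dp_la = (q_pul - q_mv + de["la"] * y[5] / e["la"] ** 2) \
                / (c.c_pulv + 1.0 / e["la"])
            assert dy[5] == pytest.approx(dp_la, rel=1e-10)

    def test_rhs_conserves_total_volume(self, unreg1, unreg4, rng):
        """The analytic d/dt of the total stressed volume vanishes along the
        RHS: the closed loop has no sources or sinks."""
        from baroloop.hemodynamics import _elastance_pair
        passive = {"1ch": [(1, "c_art"), (2, "c_ven")],
                   "4ch": [(1, "c_art"), (2, "c_ven"), (4, "c_pula"),
                           (5, "c_pulv")]}
        chamber_state = {"1ch": {"lv": 0},
                         "4ch": {"lv": 0, "rv": 3, "ra": 2, "la": 5}}
        for p in (unreg1, unreg4):
            n = 3 if p.variant == "1ch" else 6
            for _ in range(10):
                t = float(rng.uniform(0, p.tau_hr0))
                y = rng.uniform(2.0, 110.0, size=n)
                clock = ActivationClock(t, p.tau_hr0)
                dy = rhs_unregulated(y, p, clock)
                dv = 0.0
                for i, cname in passive[p.variant]:
                    dv += getattr(p.circulation, cname) * dy[i]
                for k, i in chamber_state[p.variant].items():
                    ch = p.chambers[k]
                    e, de = _elastance_pair(t, p.tau_hr0, ch.e_min, ch.e_max,
                                            ch.tau_init_frac, ch.tau_s1_frac,
                                            ch.tau_s2_frac)
                    # d(P/E)/dt = dP/E - P E'/E^2
                    dv += dy[i] / e - y[i] * de / e ** 2
                scale = max(1.0, float(np.max(np.abs(dy))))
                assert abs(dv) / scale < 1e-10

    def test_non_finite_state_rejected(self, unreg1):
        with pytest.raises(ValueError):
            rhs_unregulated(np.array([np.nan, 8.0, 8.0]), unreg1,
                            ActivationClock(0.1, 0.58))

    def test_unregulated_limit_cycle_has_base_period(self, unreg1):
        """The autonomous unregulated loop settles on a limit cycle with
        period tau_HR0."""
        traj = bl.simulate(unreg1, bl.SimulationConfig(t_end=60.0))
        tau = unreg1.tau_hr0
        t0 = 50.0
        grid = np.linspace(0.0, tau, 40, endpoint=False)
        a = np.interp(t0 + grid, traj.times, traj.states[:, 1])
        b = np.interp(t0 + tau + grid, traj.times, traj.states[:, 1])
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-3
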