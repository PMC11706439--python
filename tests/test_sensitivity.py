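"""Sensitivity machinery on closed-form oracles: local scaled derivatives,
Saltelli/Jansen Sobol estimators, bootstrap CIs, convergence, error summary."""

import math

import numpy as np
import pytest

from baroloop.sensitivity import (convergence_study, error_summary,
                                  local_sensitivity,
                                  paper_convergence_schedule, sobol_estimate,
                                  sobol_sample)


def _evaluate_design(f, design):
    fa, fb = f(design.a), f(design.b)
    fab = np.stack([f(design.ab[i]) for i in range(design.n)])
    return fa, fb, fab


# ---------------------------------------------------------------------------
# local sensitivity on toy models
# ---------------------------------------------------------------------------

class TestLocalSensitivity:
    def test_power_law_scaled_sensitivity_is_exponent(self):
        """For y = theta^2 the relative sensitivity (theta/y) dy/dtheta is
        exactly the exponent 2, independent of theta."""
        def f(x):
            x = np.atleast_2d(x)
            return (x[:, 0] ** 2)[:, None]
        for theta in (0.3, 1.7, 42.0):
            lsa = local_sensitivity(None, evaluator=(f, ["y"]),
                                    theta0=np.array([theta]))
            assert lsa.s[0, 0] == pytest.approx(2.0, rel=1e-6)
            assert np.max(lsa.richardson_error) < 1e-6

    def test_zero_influence_parameter_has_zero_entry(self):
        def f(x):
            x = np.atleast_2d(x)
            return np.column_stack([x[:, 0], 3.0 * x[:, 0]])
        lsa = local_sensitivity(None, evaluator=(f, ["a", "b"]),
                                theta0=np.array([2.0, 5.0]))
        assert np.allclose(lsa.s[1], 0.0)
        assert lsa.s[0, 0] == pytest.approx(1.0, rel=1e-6)

    def test_negative_base_parameter_handled(self):
        def f(x):
            x = np.atleast_2d(x)
            return (x[:, 0] ** 3)[:, None]
        lsa = local_sensitivity(None, evaluator=(f, ["y"]),
                                theta0=np.array([-2.0]))
        assert lsa.s[0, 0] == pytest.approx(3.0, rel=1e-6)

    def test_display_normalization_in_unit_interval(self, unreg1_lsa):
        nrm = unreg1_lsa.normalized()
        assert np.all(nrm >= 0.0) and np.all(nrm <= 1.0)
        assert np.allclose(nrm.max(axis=0), 1.0)


# ---------------------------------------------------------------------------
# Sobol design
# ---------------------------------------------------------------------------

class TestSobolSample:
    def test_design_cost_and_bounds(self):
        bounds = np.array([[0.0, 1.0], [2.0, 4.0]])
        d = sobol_sample(bounds, 4, seed=1)
        assert d.n_evaluations == 4 * (2 + 2)
        for mat in (d.a, d.b):
            assert np.all(mat[:, 0] >= 0) and np.all(mat[:, 0] <= 1)
            assert np.all(mat[:, 1] >= 2) and np.all(mat[:, 1] <= 4)
        assert not np.array_equal(d.a, d.b)
        # AB_i is A with column i from B
        assert np.array_equal(d.ab[0][:, 1], d.a[:, 1])
        assert np.array_equal(d.ab[0][:, 0], d.b[:, 0])

    def test_published_execution_counts(self):
        # K (n+2) at the full published budget
        assert 150000 * (9 + 2) == 1_650_000
        assert 150000 * (51 + 2) == 7_950_000
        assert 150000 * (36 + 2) == 5_700_000
        assert 150000 * (22 + 2) == 3_600_000

    def test_seed_determinism_bit_identical(self):
        bounds = np.array([[0.0, 1.0]] * 3)
        d1 = sobol_sample(bounds, 64, seed=7)
        d2 = sobol_sample(bounds, 64, seed=7)
        assert np.array_equal(d1.a, d2.a) and np.array_equal(d1.b, d2.b)
        d3 = sobol_sample(bounds, 64, seed=8)
        assert not np.array_equal(d1.a, d3.a)


# ---------------------------------------------------------------------------
# Sobol estimators vs closed forms
# ---------------------------------------------------------------------------

class TestSobolEstimators:
    def test_additive_linear_model_matches_variance_decomposition(self):
        """y = x1 + 2 x2 on equal uniform ranges: S1 = ST = (0.2, 0.8)."""
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        d = sobol_sample(bounds, 8192, seed=3)

        def f(x):
            return (x[:, 0] + 2.0 * x[:, 1])[:, None]

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=200, seed=3)
        for i, expect in enumerate((0.2, 0.8)):
            assert abs(res.s1[i, 0] - expect) < 3 * res.s1_ci[i, 0]
            assert abs(res.st[i, 0] - expect) < max(3 * res.st_ci[i, 0], 1e-3)
        assert res.s1[:, 0].sum() == pytest.approx(1.0, abs=0.02)

    def test_ishigami_matches_published_closed_form(self):
        """Ishigami with (a, b) = (7, 0.1): S1 = (0.3139, 0.4424, 0),
        ST = (0.5576, 0.4424, 0.2437)."""
        bounds = np.array([[-math.pi, math.pi]] * 3)
        d = sobol_sample(bounds, 8192, seed=4)

        def f(x):
            return (np.sin(x[:, 0]) + 7.0 * np.sin(x[:, 1]) ** 2
                    + 0.1 * x[:, 2] ** 4 * np.sin(x[:, 0]))[:, None]

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=200, seed=4)
        s1_exact = (0.3139, 0.4424, 0.0)
        st_exact = (0.5576, 0.4424, 0.2437)
        for i in range(3):
            assert abs(res.s1[i, 0] - s1_exact[i]) \
                < max(3 * res.s1_ci[i, 0], 5e-3)
            assert abs(res.st[i, 0] - st_exact[i]) \
                < max(3 * res.st_ci[i, 0], 5e-3)

    def test_pure_interaction_all_higher_order(self):
        """y = x1 x2 with zero-mean uniforms: S1 ~ 0, ST ~ 1."""
        bounds = np.array([[-1.0, 1.0]] * 2)
        d = sobol_sample(bounds, 8192, seed=5)

        def f(x):
            return (x[:, 0] * x[:, 1])[:, None]

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=100, seed=5)
        assert np.all(np.abs(res.s1[:, 0]) < 0.02)
        assert np.all(np.abs(res.st[:, 0] - 1.0) < 0.02)
        assert np.all(res.higher[:, 0] > 0.9)

    def test_total_order_dominates_first_order(self):
        bounds = np.array([[-math.pi, math.pi]] * 3)
        d = sobol_sample(bounds, 4096, seed=6)

        def f(x):
            return (np.sin(x[:, 0]) + 7.0 * np.sin(x[:, 1]) ** 2
                    + 0.1 * x[:, 2] ** 4 * np.sin(x[:, 0]))[:, None]

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=50, seed=6)
        noise = 3 * (res.s1_ci + res.st_ci)
        assert np.all(res.st >= res.s1 - noise)

    def test_zero_variance_output_flagged(self):
        bounds = np.array([[0.0, 1.0]] * 2)
        d = sobol_sample(bounds, 128, seed=7)

        def f(x):
            return np.full((x.shape[0], 1), 3.14)

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=10, seed=7,
                             output_names_=["const"])
        assert res.degenerate_outputs == ["const"]
        assert np.all(np.isnan(res.s1))

    def test_failed_runs_imputed_and_capped(self):
        bounds = np.array([[0.0, 1.0]] * 2)
        d = sobol_sample(bounds, 256, seed=8)

        def f(x):
            return (x[:, 0] + x[:, 1])[:, None]

        fa, fb, fab = _evaluate_design(f, d)
        fa = fa.copy()
        fa[0] = np.nan
        res = sobol_estimate(fa, fb, fab, n_boot=10, seed=8,
                             base_outputs=np.array([1.0]))
        assert res.n_failed == 1
        fa[: 2 + int(0.01 * 256)] = np.nan
        with pytest.raises(RuntimeError, match="failed"):
            sobol_estimate(fa, fb, fab, n_boot=0, seed=8,
                           base_outputs=np.array([1.0]))


# ---------------------------------------------------------------------------
# convergence and error summary
# ---------------------------------------------------------------------------

class TestConvergence:
    def test_published_schedule_shape(self):
        sched = paper_convergence_schedule()
        assert sched[:20] == [(k, 100) for k in range(100, 2001, 100)]
        assert len(sched[:20]) == 20
        assert sched[-1] == (150000, 1000)

    def test_ci_shrinks_like_root_k_on_additive_model(self):
        """Bootstrap CI half-widths scale ~K^(-1/2) on the additive toy."""
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])

        def f(x):
            return (x[:, 0] + 2.0 * x[:, 1])[:, None]

        trace = convergence_study(
            None, [(256, 100), (1024, 100), (4096, 100)], [("x0", "y0")],
            seed=9, evaluator=(f, ["y0"]), bounds=bounds,
            parameter_names=["x0", "x1"])
        s1 = trace.records[trace.records.order == "s1"]
        widths = s1.sort_values("k").ci_half_width.to_numpy()
        # 16x more samples -> ~4x narrower; allow generous slack
        assert widths[2] < widths[0] / 2.0
        slope = np.polyfit(np.log([256, 1024, 4096]), np.log(widths), 1)[0]
        assert -0.8 < slope < -0.25
        assert trace.converged_at("x0", "y0") is not None

    def test_error_summary_aggregates_ci(self):
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        d = sobol_sample(bounds, 2048, seed=10)

        def f(x):
            return (x[:, 0] + 2.0 * x[:, 1])[:, None]

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=100, seed=10)
        err = error_summary(res)
        assert err["s1"]["min"] <= err["s1"]["mean"] <= err["s1"]["max"]
        # the Jansen total-order estimator is tighter than the Saltelli
        # first-order one on an additive response
        assert err["st"]["mean"] < err["s1"]["mean"]

    def test_error_summary_single_entry_is_its_mean(self):
        bounds = np.array([[0.0, 1.0]])
        d = sobol_sample(bounds, 512, seed=11)

        def f(x):
            return (x[:, 0] ** 2)[:, None]

        res = sobol_estimate(*_evaluate_design(f, d), n_boot=50, seed=11)
        err = error_summary(res)
        assert err["s1"]["mean"] == pytest.approx(float(res.s1_ci[0, 0]))
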