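import math

import numpy as np
import pytest
from scipy.optimize import brentq

import nicholson as nc
from conftest import constant_model, flat_history, synthetic_draw


class TestCumulativeAlpha:
    def test_constant_rate_closed_form(self):
        model = constant_model(alpha=2.5)
        assert nc.cumulative_alpha(model, 4.0) == pytest.approx(10.0, abs=1e-10)

    def test_log_closed_form(self):
        model = constant_model()
        model.alpha = nc.TimeFunction.from_expression("1/(1+t)")
        A = nc.CumulativeAlpha(model)
        assert A(math.e - 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_negative_below_t0(self, eq21):
        model, _ = eq21
        A = nc.CumulativeAlpha(model)
        assert A(-0.5) < 0 < A(0.5)

    def test_matches_riemann_oracle(self):
        model, _ = synthetic_draw(5)
        A = nc.CumulativeAlpha(model)
        h = 1e-5
        grid = np.arange(0.0, 3.0, h) + h / 2
        riemann = h * sum(model.alpha(float(t)) for t in grid)
        assert abs(A(3.0) - riemann) < 1e-4

    def test_incremental_cache_consistency(self, eq21):
        model, _ = eq21
        A = nc.CumulativeAlpha(model)
        walked = [A(t) for t in np.linspace(0.0, 20.0, 200)]
        fresh = nc.CumulativeAlpha(model)(20.0)
        assert walked[-1] == pytest.approx(fresh, abs=1e-9)
        assert all(b >= a - 1e-12 for a, b in zip(walked, walked[1:]))


class TestAssumptions:
    def test_declared_metadata_passthrough(self):
        model, _ = nc.generate_synthetic_model(p=1.0, c=[0.5], seed=7)
        report = nc.check_assumptions(model)
        assert report.a2.holds is True
        assert report.a3.holds is True
        assert report.a3.limsup_value == pytest.approx(0.5)

    def test_declared_convergent_integral(self):
        model = constant_model()
        model.alpha = nc.TimeFunction.from_expression(
            "1/(1+t)^2",
            meta=nc.AsymptoticMeta(integral_diverges=False),
        )
        report = nc.check_assumptions(model)
        assert report.a2.holds is False

    def test_numeric_probe_discriminates_divergence(self):
        # no declarations at all: the dyadic-window probe must separate
        # the divergent 1/(1+t) tail from the convergent 1/(1+t)^2 tail
        for expr, expected in [("1/(1+t)", True), ("1/(1+t)^2", False)]:
            model = constant_model()
            model.alpha = nc.TimeFunction.from_expression(expr)
            report = nc.check_assumptions(model)
            assert report.a2.holds is expected, expr
            assert report.source in ("numeric_probe", "mixed")

    def test_eq21_m_alpha_value(self, eq21_report):
        # worst delay window sits at t = 0 with tau = 1:
        # int_{-1}^{0} 2/(2+s) ds = 2 ln 2
        assert eq21_report.a1.m_alpha == pytest.approx(2 * math.log(2), abs=1e-8)

    def test_declared_probe_disagreement_warns(self):
        model, _ = nc.generate_synthetic_model(p=1.0, c=[2.0], seed=1)
        model.meta["ratio_limsup"] = 0.5  # wrong on purpose
        report = nc.check_assumptions(model)
        assert report.a3.limsup_value == pytest.approx(0.5)  # declaration wins
        assert any("A3" in w for w in report.warnings)

    def test_unbounded_window_integral_fails_a1(self, eq9):
        model, _ = eq9
        report = nc.check_assumptions(model)
        assert report.a1.holds is False
        assert report.a1.m_alpha is None


class TestUltimateBound:
    def test_eq21_delta_value_and_eventual_bound(self, eq21, eq21_report,
                                                 eq21_trajectory):
        model, history = eq21
        ub = nc.ultimate_bound(model, eq21_report)
        # gamma = 1 and ratio = 1/2 everywhere: delta = 1/(2e)
        assert ub.delta == pytest.approx(0.5 / math.e, abs=1e-6)
        assert ub.onset_time == model.t0
        times = eq21_trajectory.solution_times()
        tail = eq21_trajectory.solution_values()[times >= 40.0]
        assert (tail <= ub.delta * (1 + 1e-6)).all()

    def test_transient_envelope_holds_pointwise(self, eq21, eq21_report,
                                                eq21_trajectory):
        model, history = eq21
        ub = nc.ultimate_bound(model, eq21_report)
        env = nc.transient_envelope(model, ub, history.sup_norm())
        for t, x in zip(eq21_trajectory.solution_times()[::10],
                        eq21_trajectory.solution_values()[::10]):
            assert x <= env(float(t)) * (1 + 1e-6)

    def test_eventual_bound_on_constant_models(self):
        """Sweep of random flat histories: all end up below delta."""
        model = constant_model(alpha=1.0, beta=(0.5,), gamma=(1.0,))
        report = nc.check_assumptions(model)
        ub = nc.ultimate_bound(model, report)
        rng = np.random.default_rng(42)
        for x0 in rng.uniform(0.05, 5.0, size=10):
            traj = nc.simulate(model, flat_history(model, float(x0)),
                               nc.SolverConfig(step=0.01, horizon=30.0))
            assert traj.values[-1] <= ub.delta * (1 + 1e-6)

    def test_requires_a3(self):
        model, _ = nc.generate_synthetic_model(p=1.0, c=[2.0], seed=1)
        report = nc.check_assumptions(model)
        with pytest.raises(nc.AssumptionError, match="A3"):
            nc.ultimate_bound(model, report)


class TestRootSolver:
    def test_linear(self):
        assert nc.solve_increasing_root(lambda x: x - 1.0) == pytest.approx(
            1.0, abs=1e-10)

    def test_transcendental_frozen_value(self):
        # root of x + e^x = 2, located independently by dense sign scan
        f = lambda x: x + math.exp(x) - 2.0
        root = nc.solve_increasing_root(f)
        assert abs(f(root)) <= 1e-10
        assert root == pytest.approx(0.4428544010, abs=1e-8)

    def test_no_positive_root(self):
        with pytest.raises(nc.RootFindError):
            nc.solve_increasing_root(lambda x: x + 1.0)

    def test_never_crossing_errors(self):
        with pytest.raises(nc.RootFindError, match="doublings"):
            nc.solve_increasing_root(lambda x: -1.0 / (1.0 + x))

    def test_against_brentq_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            a = float(rng.uniform(0.1, 3.0))
            b = float(rng.uniform(0.1, 2.0))
            c = float(rng.uniform(0.1, 2.0))
            d = float(rng.uniform(0.5, 4.0))
            f = lambda x: a * x + b * (math.exp(c * x) - 1.0) - d
            ours = nc.solve_increasing_root(f)
            ref = brentq(f, 1e-12, 100.0, xtol=1e-13, rtol=1e-15)
            assert abs(ours - ref) < 1e-8


class TestDecayRate:
    def test_eq21_lambda_star(self, eq21, eq21_report):
        model, history = eq21
        est = nc.decay_rate(model, eq21_report, history.sup_norm())
        # unique positive root of lambda - 1 + 0.5 e^{2 ln2 lambda} = 0
        assert est.residual <= 1e-10
        assert est.characteristic(est.lambda_star - 1e-6) < 0
        assert est.characteristic(est.lambda_star + 1e-6) > 0
        assert est.lambda_star == pytest.approx(0.2715002204, abs=1e-6)
        assert est.onset_time == model.t0
        assert est.prefactor == pytest.approx(history.sup_norm())

    def test_gate_on_failed_assumptions(self):
        model, history = nc.generate_synthetic_model(p=1.0, c=[2.0], seed=1)
        report = nc.check_assumptions(model)
        with pytest.raises(nc.AssumptionError):
            nc.decay_rate(model, report, history.sup_norm())

    def test_envelope_nonincreasing_and_vanishing(self, eq21, eq21_report):
        model, history = eq21
        est = nc.decay_rate(model, eq21_report, history.sup_norm())
        vals = [est.envelope(t) for t in (10.0, 100.0, 1000.0, 10000.0)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        grid = np.linspace(0.0, 50.0, 301)
        env = [est.envelope(float(t)) for t in grid]
        assert all(b <= a + 1e-15 for a, b in zip(env, env[1:]))

    def test_lambda_star_monotone_in_production_ratio(self):
        """Weaker production (smaller c) never slows the certified decay."""
        lams = []
        for c in np.arange(0.1, 1.0, 0.1):
            model, history = nc.generate_synthetic_model(p=1.0, c=[float(c)],
                                                         seed=9)
            report = nc.check_assumptions(model)
            est = nc.decay_rate(model, report, history.sup_norm())
            lams.append(est.lambda_star)
        assert all(a >= b - 1e-12 for a, b in zip(lams, lams[1:]))


class TestConstantRate:
    def test_pure_decay_limit(self):
        model = constant_model(alpha=1.0, beta=(0.0,))
        assert nc.constant_rate(model) == pytest.approx(1.0, abs=1e-10)

    def test_residual_and_envelope_bound(self):
        model = constant_model(alpha=1.0, beta=(0.5,), gamma=(1.0,), tau=(1.0,))
        eta = nc.constant_rate(model)
        assert abs(eta - 1.0 + 0.5 * math.exp(eta)) <= 1e-10
        rng = np.random.default_rng(7)
        for x0 in rng.uniform(0.1, 2.0, size=5):
            traj = nc.simulate(model, flat_history(model, float(x0)),
                               nc.SolverConfig(step=0.01, horizon=20.0))
            env = float(x0) * np.exp(-eta * traj.solution_times())
            assert (traj.solution_values() <= env * (1 + 1e-6)).all()

    def test_time_varying_without_declared_bounds_errors(self, eq21):
        model, _ = eq21
        with pytest.raises(nc.AnalysisError, match="declared"):
            nc.constant_rate(model)

    def test_declared_bounds_path(self, eq21):
        model, _ = eq21
        model2 = nc.NicholsonModel(
            alpha=model.alpha, betas=model.betas, gammas=model.gammas,
            taus=model.taus, tau_max=model.tau_max, t0=model.t0,
            meta={"alpha_lower": 0.5, "beta_upper": [0.125, 0.125]},
        )
        eta = nc.constant_rate(model2)
        assert eta > 0
        assert abs(eta - 0.5 + 0.25 * math.exp(eta)) <= 1e-10

    @pytest.mark.parametrize("alpha,beta,gamma,tau", [
        (1.0, 0.5, 1.0, 1.0),
        (2.0, 0.6, 0.5, 0.4),
        (0.7, 0.2, 2.0, 0.9),
        (1.5, 1.0, 1.0, 0.2),
    ])
    def test_consistency_with_generalized_rate(self, alpha, beta, gamma, tau):
        """For constant coefficients the generalized envelope must coincide
        with the classical one: eta = lambda_star * alpha exactly."""
        model = constant_model(alpha=alpha, beta=(beta,), gamma=(gamma,),
                               tau=(tau,))
        report = nc.check_assumptions(model)
        est = nc.decay_rate(model, report, 1.0)
        eta = nc.constant_rate(model)
        assert abs(est.lambda_star * alpha - eta) < 1e-10
        for t in np.linspace(0.0, 10.0, 21):
            general = est.envelope(float(t))
            classical = est.prefactor * math.exp(-eta * float(t))
            assert general == pytest.approx(classical, rel=1e-9)
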