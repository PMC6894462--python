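"""Unit and property tests for the pooled modified Poisson fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modpois import (
    ConfigurationError,
    ConvergenceConfig,
    DesignData,
    FitResult,
    ModelSpec,
    NonConvergenceError,
    NumericalOverflowError,
    SingularSystemError,
    ValidationError,
    build_design,
    check_convergence,
    fit_pooled,
    newton_step,
    risk_ratio_report,
    sandwich_variance,
    score_and_hessian,
)

from conftest import make_2x2, random_dataset


class TestModelSpec:
    def test_term_order_is_intercept_exposure_covariates_interactions(self):
        spec = ModelSpec(covariate_names=("a", "b"), interaction_terms=("b",))
        assert spec.term_names == ["Intercept", "Exposure", "a", "b", "Exposure:b"]
        assert spec.n_terms == 5
        assert spec.exposure_index == 1

    def test_multicenter_study_design_has_seven_terms(self):
        spec = ModelSpec(covariate_names=("X1", "X2", "X3", "X4", "X5"))
        assert spec.term_names == [
            "Intercept", "Exposure", "X1", "X2", "X3", "X4", "X5",
        ]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(covariate_names=("a", "a")),
            dict(covariate_names=("a",), interaction_terms=("zzz",)),
            dict(covariate_names=("a",), include_intercept=False),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelSpec(**kwargs)


class TestBuildDesign:
    def test_main_effects_layout(self):
        spec = ModelSpec(covariate_names=("x1",))
        d = build_design([1, 0], [[2.0], [3.0]], spec)
        np.testing.assert_array_equal(d.Z, [[1, 1, 2], [1, 0, 3]])

    def test_interaction_column_is_exposure_times_covariate(self):
        spec = ModelSpec(covariate_names=("x1",), interaction_terms=("x1",))
        d = build_design([1, 0], [[2.0], [3.0]], spec)
        np.testing.assert_array_equal(d.Z, [[1, 1, 2, 2], [1, 0, 3, 0]])

    def test_nonbinary_exposure_rejected(self):
        spec = ModelSpec(covariate_names=("x1",))
        with pytest.raises(ValidationError, match="binary"):
            build_design([1, 2], [[1.0], [1.0]], spec)

    def test_unknown_covariate_label_rejected(self):
        import pandas as pd

        spec = ModelSpec(covariate_names=("nope",))
        with pytest.raises(ConfigurationError, match="nope"):
            build_design([1, 0], pd.DataFrame({"x1": [1.0, 2.0]}), spec)

    def test_nonbinary_outcome_rejected(self):
        spec = ModelSpec(covariate_names=("x1",))
        with pytest.raises(ValidationError, match="binary"):
            build_design([1, 0], [[1.0], [1.0]], spec, y=[0.5, 0])


class TestScoreAndHessian:
    def test_intercept_only_at_zero(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        d = DesignData(Z=np.ones((10, 1)), y=y)
        S, H = score_and_hessian(d, np.zeros(1))
        assert S[0] == pytest.approx(10 * (0.3 - 1.0))
        assert H[0, 0] == pytest.approx(-10.0)

    def test_saturated_2x2_score_zero_at_cell_proportions(self):
        # exposed risk 10/20 = 0.5, unexposed 5/20 = 0.25 -> beta = (log .25, log 2)
        d = make_2x2()
        S, _ = score_and_hessian(d, np.array([np.log(0.25), np.log(2.0)]))
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_score_zero_at_fitted_root(self):
        rng = np.random.default_rng(7)
        d = random_dataset(rng, n=300, p=4)
        fit = fit_pooled(d)
        S, _ = score_and_hessian(d, fit.beta)
        assert np.max(np.abs(S)) < 1e-6 * d.n

    def test_overflow_raises_named_error(self):
        d = DesignData(Z=np.column_stack([np.ones(3), [1000.0, 0, 0]]), y=[1, 0, 1])
        with pytest.raises(NumericalOverflowError, match="700"):
            score_and_hessian(d, np.array([0.0, 1.0]))

    def test_hessian_negative_semidefinite(self):
        rng = np.random.default_rng(11)
        d = random_dataset(rng, n=200, p=3)
        _, H = score_and_hessian(d, rng.normal(scale=0.2, size=3))
        assert np.max(np.linalg.eigvalsh(H)) <= 1e-10


class TestNewtonStep:
    def test_zero_score_is_fixed_point(self):
        b = np.array([0.3, -0.2])
        out = newton_step(b, np.zeros(2), -np.eye(2))
        np.testing.assert_array_equal(out, b)

    def test_scalar_arithmetic(self):
        out = newton_step(np.array([1.0]), np.array([2.0]), np.array([[-4.0]]))
        assert out[0] == pytest.approx(1.5)

    def test_intercept_only_first_step_and_limit(self):
        # score at 0 is n(ybar - 1), Hessian -n: one step gives ybar - 1;
        # iterating solves sum(y - exp(b0)) = 0, i.e. b0 = log(ybar)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        d = DesignData(Z=np.ones((10, 1)), y=y)
        S, H = score_and_hessian(d, np.zeros(1))
        assert newton_step(np.zeros(1), S, H)[0] == pytest.approx(0.3 - 1.0)
        fit = fit_pooled(d)
        assert fit.beta[0] == pytest.approx(np.log(0.3), abs=1e-12)

    def test_singular_hessian_names_suspect_columns(self):
        H = -np.array([[2.0, 2.0], [2.0, 2.0]])  # rank 1
        with pytest.raises(SingularSystemError, match="suspect columns"):
            newton_step(np.zeros(2), np.array([1.0, 1.0]), H)


class TestCheckConvergence:
    cfg = ConvergenceConfig(tol=1e-8)

    @pytest.mark.parametrize(
        "prev, new, expect_conv, expect_delta",
        [
            ([0.005], [0.005 + 5e-9], True, 5e-9),  # absolute branch
            ([1.0], [1.0 + 5e-9], True, 5e-9),  # relative branch
            ([0.02], [0.02 + 3e-10], False, 1.5e-8),  # relative, just over tol
        ],
    )
    def test_branch_selection_and_threshold(self, prev, new, expect_conv, expect_delta):
        conv, deltas = check_convergence(np.array(prev), np.array(new), self.cfg)
        assert conv is expect_conv
        assert deltas[0] == pytest.approx(expect_delta, rel=1e-6)

    def test_switch_is_strict_at_boundary(self):
        # |beta_prev| exactly at the threshold takes the relative branch
        conv, deltas = check_convergence(
            np.array([0.01]), np.array([0.01 + 2e-10]), self.cfg
        )
        assert deltas[0] == pytest.approx(2e-8, rel=1e-6)
        assert not conv

    def test_negative_relative_branch_uses_signed_denominator(self):
        _, deltas = check_convergence(np.array([-2.0]), np.array([-2.0 + 1e-8]), self.cfg)
        assert deltas[0] == pytest.approx(-5e-9, rel=1e-6)


class TestFitPooled:
    def test_intercept_only_closed_form(self):
        n, k = 200, 60  # 30% events
        y = np.zeros(n); y[:k] = 1
        fit = fit_pooled(DesignData(Z=np.ones((n, 1)), y=y))
        assert fit.beta[0] == pytest.approx(np.log(0.3), abs=1e-10)
        assert fit.se[0] == pytest.approx(np.sqrt(0.7 / (n * 0.3)), rel=1e-10)

    def test_2x2_crude_risk_ratio_closed_form(self):
        fit = fit_pooled(make_2x2())
        assert fit.beta[1] == pytest.approx(np.log(2.0), abs=1e-10)
        assert fit.se[1] == pytest.approx(np.sqrt(0.2), rel=1e-10)

    def test_trace_records_every_iterate_and_score_is_zero(self):
        rng = np.random.default_rng(3)
        d = random_dataset(rng, n=400, p=5)
        fit = fit_pooled(d)
        assert len(fit.trace) == fit.n_iterations
        np.testing.assert_array_equal(fit.trace[-1][0], fit.beta)
        S, _ = score_and_hessian(d, fit.beta)
        assert np.max(np.abs(S)) < 1e-6 * d.n

    def test_nonconvergence_error_carries_trace(self):
        rng = np.random.default_rng(5)
        d = random_dataset(rng, n=300, p=4)
        with pytest.raises(NonConvergenceError) as exc:
            fit_pooled(d, cfg=ConvergenceConfig(max_iterations=2))
        assert len(exc.value.trace) == 2

    def test_constant_column_rejected_before_fitting(self):
        Z = np.column_stack([np.ones(50), np.full(50, 2.0)])
        y = np.zeros(50); y[:10] = 1
        with pytest.raises(ValidationError, match="constant"):
            fit_pooled(DesignData(Z=Z, y=y))

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        d = random_dataset(rng, n=250, p=4)
        perm = rng.permutation(d.n)
        fit1 = fit_pooled(d)
        fit2 = fit_pooled(DesignData(Z=d.Z[perm], y=d.y[perm]))
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_covariance_symmetric_psd_and_se_consistent(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dataset(rng)
        fit = fit_pooled(d)
        np.testing.assert_allclose(fit.cov, fit.cov.T, rtol=1e-10)
        eigs = np.linalg.eigvalsh(fit.cov)
        assert eigs[0] >= -1e-10 * eigs[-1]
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(fit.cov)))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_glm_poisson_hc0_oracle(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        d = random_dataset(rng)
        try:
            fit = fit_pooled(d)
        except NonConvergenceError:
            return
        glm = sm.GLM(d.y, d.Z, family=sm.families.Poisson()).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.beta, glm.params, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(fit.se, glm.bse, rtol=1e-6)


class TestSandwichVariance:
    def test_intercept_only_closed_form(self):
        n, k = 120, 36
        y = np.zeros(n); y[:k] = 1
        d = DesignData(Z=np.ones((n, 1)), y=y)
        cov = sandwich_variance(d, np.array([np.log(k / n)]))
        assert cov[0, 0] == pytest.approx((1 - k / n) / (n * k / n), rel=1e-12)

    def test_zero_residuals_give_zero_matrix(self):
        d = DesignData(Z=np.ones((30, 1)), y=np.ones(30))
        cov = sandwich_variance(d, np.zeros(1))  # mu = 1 = y everywhere
        np.testing.assert_array_equal(cov, np.zeros((1, 1)))

    def test_fitted_risk_above_one_logs_warning(self, caplog):
        import logging

        d = DesignData(Z=np.column_stack([np.ones(20), np.linspace(0, 1, 20)]),
                       y=np.r_[np.ones(10), np.zeros(10)])
        with caplog.at_level(logging.WARNING, logger="modpois.model"):
            sandwich_variance(d, np.array([0.05, 0.1]))
        assert any("fitted" in rec.message for rec in caplog.records)


class TestRiskRatioReport:
    def _fit(self, beta, se, names=()):
        spec = ModelSpec(covariate_names=names)
        p = len(beta)
        return (
            FitResult(
                beta=np.asarray(beta, float),
                cov=np.diag(np.square(se)),
                se=np.asarray(se, float),
                n_iterations=5,
                converged=True,
                trace=[],
                term_names=spec.term_names,
            ),
            spec,
        )

    def test_null_effect_gives_unit_rr_centered_ci(self):
        fit, spec = self._fit([np.log(0.3), 0.0], [0.05, 0.1])
        row = risk_ratio_report(fit, spec).iloc[1]
        assert row.RR == pytest.approx(1.0)
        assert row.CI_low < 1.0 < row.CI_high
        assert row.CI_low * row.CI_high == pytest.approx(1.0, rel=1e-10)

    def test_printed_numbers_worked_example(self):
        # reconstruct RR 0.63 (0.58, 0.68) from estimate -0.4632219, SE 0.0422368
        fit, spec = self._fit([-1.5, -0.4632219], [0.10, 0.0422368])
        row = risk_ratio_report(fit, spec, z_value=1.96).iloc[1]
        assert round(row.RR, 2) == 0.63
        assert (round(row.CI_low, 2), round(row.CI_high, 2)) == (0.58, 0.68)

    def test_interaction_rr_depends_on_x_and_needs_at_x(self):
        spec = ModelSpec(covariate_names=("x1",), interaction_terms=("x1",))
        beta = np.array([-1.0, -0.5, 0.2, 0.3])
        cov = np.diag([0.01, 0.04, 0.01, 0.02])
        fit = FitResult(beta=beta, cov=cov, se=np.sqrt(np.diag(cov)),
                        n_iterations=4, converged=True, trace=[],
                        term_names=spec.term_names)
        with pytest.raises(ConfigurationError, match="at_x"):
            risk_ratio_report(fit, spec)
        tab = risk_ratio_report(fit, spec, at_x={"x1": 2.0})
        combo = tab.iloc[-1]
        assert combo.estimate == pytest.approx(-0.5 + 0.3 * 2.0)
        assert combo.se == pytest.approx(np.sqrt(0.04 + 4 * 0.02))

    def test_zero_interaction_coefficient_gives_constant_rr(self):
        spec = ModelSpec(covariate_names=("x1",), interaction_terms=("x1",))
        beta = np.array([-1.0, -0.5, 0.2, 0.0])
        cov = np.diag([0.01, 0.04, 0.01, 0.0])
        fit = FitResult(beta=beta, cov=cov, se=np.sqrt(np.diag(cov)),
                        n_iterations=4, converged=True, trace=[],
                        term_names=spec.term_names)
        for x in (0.0, 1.0, 5.0):
            tab = risk_ratio_report(fit, spec, at_x={"x1": x})
            assert tab.iloc[-1].RR == pytest.approx(np.exp(-0.5))
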