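"""Unit and property tests for the mean/variance model fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mvqtl import mvmodels
from mvqtl.mvmodels import (
    DegenerateDataError,
    DesignError,
    DesignSpec,
    SmallGroupError,
    fit_dglm,
    fit_group_variance_model,
    fit_normal_linear,
    levene_W,
    normal_loglik,
)


def intercept_design(n, mean_cols=None):
    return DesignSpec.build(n, mean_covariates=mean_cols)


class TestNormalLinear:
    def test_intercept_only_ml_estimates(self):
        fit = fit_normal_linear([1.0, 2.0, 3.0], intercept_design(3))
        assert np.allclose(fit.fitted_means, 2.0)
        assert fit.variance_coefficients[0] == pytest.approx(2.0 / 3.0)
        # exact log-likelihood at the ML estimates
        assert fit.log_likelihood == pytest.approx(
            -1.5 * np.log(2 * np.pi * 2 / 3) - 1.5, abs=1e-12
        )
        assert fit.converged and fit.n_iterations == 1

    def test_residuals_and_variance_invariants(self, rng):
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 2))
        fit = fit_normal_linear(y, intercept_design(40, X))
        assert np.allclose(fit.residuals, y - fit.fitted_means)
        assert np.all(fit.fitted_variances > 0)
        assert np.ptp(fit.fitted_variances) == 0.0  # homoskedastic
        assert fit.log_likelihood == pytest.approx(
            normal_loglik(fit.residuals, fit.fitted_variances), abs=1e-8
        )

    def test_duplicated_column_is_design_error(self):
        x = np.arange(6.0)
        with pytest.raises(DesignError):
            intercept_design(6, np.column_stack([x, x]))

    def test_too_few_observations(self):
        with pytest.raises(mvmodels.InsufficientDataError):
            fit_normal_linear([1.0, 2.0], intercept_design(2, np.array([[1.0], [2.0]])))


class TestDGLM:
    def test_homoskedastic_limit_matches_slm(self, rng):
        """Intercept-only variance design: DGLM collapses to the SLM."""
        for _ in range(100):
            n = int(rng.integers(20, 80))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = X @ rng.normal(size=3) + rng.normal(size=n) * rng.uniform(0.5, 2)
            design = DesignSpec(X, np.ones((n, 1)))
            slm = fit_normal_linear(y, design)
            dglm = fit_dglm(y, design)
            assert abs(dglm.log_likelihood - slm.log_likelihood) < 1e-6
            assert np.allclose(dglm.mean_coefficients, slm.mean_coefficients, atol=1e-6)

    def test_matches_independent_statsmodels_iteration(self, rng):
        """Joint ML solution agrees with an independently-built alternating
        WLS / gamma-GLM fit from statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(5):
            n = 150
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            Z = np.column_stack([np.ones(n), rng.normal(size=(n, 1))])
            y = X @ [1.0, 0.5, -0.3] + rng.normal(size=n) * np.exp(0.5 * Z @ [0.1, 0.5])
            fit = fit_dglm(y, DesignSpec(X, Z))
            sigma2 = np.full(n, np.var(y))
            for _ in range(300):
                mfit = sm.WLS(y, X, weights=1.0 / sigma2).fit()
                resid = y - mfit.fittedvalues
                vfit = sm.GLM(
                    resid**2, Z, family=sm.families.Gamma(sm.families.links.Log())
                ).fit()
                sigma2 = vfit.fittedvalues
            assert abs(fit.log_likelihood - normal_loglik(resid, sigma2)) < 1e-6
            assert np.allclose(fit.mean_coefficients, mfit.params, atol=1e-5)
            assert np.allclose(fit.variance_coefficients, vfit.params, atol=1e-5)

    def test_variance_effect_recovery_at_large_n(self):
        """The background log-variance pattern of the block covariate is
        recovered at n=3000: the joint standardized error of the five
        per-level log-variance estimates (each with Var ~ 2/n_g) is within
        the chi-square(5) 99.9% envelope, and each level is within 4 SE."""
        from mvqtl import simstudy

        n = 3000
        rng = np.random.default_rng(7)
        covariate = simstudy.covariate_blocks(n)
        gamma = simstudy.GAMMA_BVH
        y = rng.normal(0.0, np.exp(gamma[covariate - 1]), size=n)
        cols = (covariate[:, None] == np.arange(2, 6)[None, :]).astype(float)
        fit = fit_dglm(y, DesignSpec.build(n, variance_covariates=cols))
        assert fit.converged
        # per-level fitted log variance = intercept + level coefficient
        est = fit.variance_coefficients[0] + np.concatenate(
            [[0.0], fit.variance_coefficients[1:]]
        )
        truth = 2.0 * gamma  # generative log sigma^2 per level
        se = np.sqrt(2.0 / 600)
        z = (est - truth) / se
        assert np.all(np.abs(z) < 4.0)
        assert np.sum(z**2) < stats.chi2.ppf(0.999, 5)

    def test_constant_phenotype_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_dglm(np.ones(30), intercept_design(30))

    def test_nonconvergence_is_flagged_and_raisable(self, rng):
        n = 60
        covs = rng.normal(size=(n, 2))
        y = rng.normal(size=n) * np.exp(covs @ [0.5, -0.5])
        design = DesignSpec.build(n, variance_covariates=covs)
        fit = fit_dglm(y, design, max_iter=1)
        assert not fit.converged
        with pytest.raises(mvmodels.NonConvergenceError) as err:
            fit_dglm(y, design, max_iter=1, on_nonconvergence="raise")
        assert err.value.fit.n_iterations == 1


class TestGroupVarianceModel:
    def test_single_group_reduces_to_slm(self, rng):
        y = rng.normal(size=30)
        slm = fit_normal_linear(y, intercept_design(30))
        cao = fit_group_variance_model(y, intercept_design(30), np.zeros(30, dtype=int))
        assert cao.log_likelihood == pytest.approx(slm.log_likelihood, abs=1e-8)
        assert cao.variance_coefficients[0] == pytest.approx(slm.variance_coefficients[0])

    def test_two_group_fit_beats_likelihood_grid(self, rng):
        """ML fit must (weakly) dominate a brute-force profile-likelihood
        grid over the shared mean, to 1e-3 in log-likelihood."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            y = np.concatenate([r.normal(0, 1, 6), r.normal(0.5, 3, 6)])
            g = np.repeat([0, 1], 6)
            fit = fit_group_variance_model(y, intercept_design(12), g)
            grid_best = -np.inf
            for mu in np.linspace(y.min(), y.max(), 600):
                resid = y - mu
                phi = np.array([np.mean(resid[g == 0] ** 2), np.mean(resid[g == 1] ** 2)])
                grid_best = max(grid_best, normal_loglik(resid, phi[g]))
            assert fit.log_likelihood >= grid_best - 1e-3
            assert abs(fit.log_likelihood - grid_best) < 1e-2

    def test_small_group_errors(self):
        with pytest.raises(SmallGroupError):
            fit_group_variance_model(
                np.arange(5.0), intercept_design(5), np.array([0, 0, 0, 0, 1])
            )

    def test_empty_declared_level_warns(self, caplog, rng):
        y = rng.normal(size=10)
        with caplog.at_level("WARNING"):
            fit_group_variance_model(
                y, intercept_design(10), np.repeat([0, 1], 5), levels=np.array([0, 1, 2])
            )
        assert any("empty" in m for m in caplog.messages)


class TestLevene:
    def test_identical_deviation_profiles_give_zero(self):
        comp = levene_W([0, 2, 4, 1, 3, 5], [0, 0, 0, 1, 1, 1])
        assert comp.W == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        comp = levene_W([1, 2, 3, 2, 4, 6], [0, 0, 0, 1, 1, 1])
        assert comp.W == pytest.approx(0.8, abs=1e-12)
        assert np.allclose(comp.group_deviation_means, [2 / 3, 4 / 3])
        assert comp.df_num == 1 and comp.df_den == 4
        assert comp.p_value == pytest.approx(stats.f.sf(0.8, 1, 4))

    def test_matches_scipy_mean_centered_levene(self, rng):
        y = rng.normal(size=60) * np.repeat([1.0, 2.5, 0.7], 20)
        g = np.repeat([0, 1, 2], 20)
        W, p = stats.levene(y[:20], y[20:40], y[40:], center="mean")
        comp = levene_W(y, g)
        assert comp.W == pytest.approx(W)
        assert comp.p_value == pytest.approx(p)

    def test_reduces_to_anova_f_under_deviation_substitution(self, rng):
        """Applying the same ratio to the raw phenotype instead of the
        deviations gives the one-way ANOVA F statistic."""
        y = rng.normal(size=30) + np.repeat([0.0, 1.0, 2.0], 10)
        g = np.repeat([0, 1, 2], 10)
        # Levene's W *is* the ANOVA F on the absolute deviations
        comp = levene_W(y, g)
        z = comp.abs_deviations
        F, _ = stats.f_oneway(z[:10], z[10:20], z[20:])
        assert comp.W == pytest.approx(F)

    def test_small_group_error(self):
        with pytest.raises(SmallGroupError):
            levene_W([1.0, 2.0, 3.0], [0, 0, 1])


class TestLikelihoodStructure:
    def test_nesting_of_log_likelihoods(self, rng):
        """Richer variance models can never fit worse than the SLM."""
        n = 90
        g = rng.integers(0, 3, size=n)
        y = rng.normal(size=n) * (1.0 + g)
        design = intercept_design(n)
        slm = fit_normal_linear(y, design)
        cao = fit_group_variance_model(y, design, g)
        gcols = (g[:, None] == [1, 2]).astype(float)
        dglm = fit_dglm(y, DesignSpec.build(n, variance_covariates=gcols))
        assert cao.log_likelihood >= slm.log_likelihood - 1e-8
        assert dglm.log_likelihood >= slm.log_likelihood - 1e-8

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(0.1, 10, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_location_scale_equivariance(self, a, b, seed):
        """Affine rescaling y -> a + b*y shifts every log-likelihood by
        exactly -n*log(b) and leaves LR statistics unchanged."""
        rng = np.random.default_rng(seed)
        n = 45
        g = np.repeat([0, 1, 2], 15)
        y = rng.normal(size=n) * (1 + 0.3 * g) + 0.2 * g
        design = intercept_design(n)
        gcols = (g[:, None] == [1, 2]).astype(float)
        vdesign = DesignSpec.build(n, variance_covariates=gcols)
        shift = -n * np.log(b)
        for fitter in (
            lambda yy: fit_normal_linear(yy, design),
            lambda yy: fit_group_variance_model(yy, design, g),
            lambda yy: fit_dglm(yy, vdesign),
        ):
            f1, f2 = fitter(y), fitter(a + b * y)
            assert f2.log_likelihood - f1.log_likelihood == pytest.approx(
                shift, abs=1e-5
            )
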