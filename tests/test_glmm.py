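"""Unit and oracle tests for the AGQ mixed-model fitter.

The sigma_u = 0 limit is checked against statsmodels (an independent GLM
implementation used only as a test oracle); the quadrature is checked
against dense trapezoid integration over the random effect.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from migenv import glmm
from migenv.glmm import ModelSpec, fit_glmm, marginal_loglik


def two_by_two(a=50, b=50, c=25, d=75):
    rows = []
    for x, y, n in [(1, 1, a), (1, 0, b), (0, 1, c), (0, 0, d)]:
        rows += [{"x": x, "y": y, "county": "A" if i % 2 else "B"} for i in range(n)]
    return pd.DataFrame(rows)


def simulate_logistic(n, n_groups, beta, sigma, seed, x_sd=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, x_sd, n)
    g = rng.integers(0, n_groups, n)
    u = rng.normal(0, sigma, n_groups)
    eta = beta[0] + beta[1] * x + u[g]
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "x": x, "county": g})


class TestGlmLimit:
    def test_2x2_cross_product_or(self):
        fit = fit_glmm(
            ModelSpec(family="logistic", outcome="y", exposure="x", fix_sigma=0.0),
            two_by_two(),
        )
        assert fit.effect_estimate == pytest.approx(3.0, abs=1e-6)
        assert fit.converged

    def test_logistic_matches_statsmodels(self):
        df = simulate_logistic(600, 4, (0.3, 0.5), 0.4, seed=1)
        fit = fit_glmm(
            ModelSpec(family="logistic", outcome="y", exposure="x", fix_sigma=0.0), df
        )
        oracle = sm.GLM(
            df["y"], sm.add_constant(df["x"]), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)

    def test_negbin_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        n = 700
        x = rng.normal(0, 1, n)
        py = rng.uniform(0.5, 3.0, n)
        mu = py * np.exp(0.2 + 0.5 * x)
        y = rng.poisson(rng.gamma(1 / 0.6, 0.6 * mu))
        df = pd.DataFrame({"y": y, "x": x, "county": rng.integers(0, 4, n), "py": py})
        fit = fit_glmm(
            ModelSpec(
                family="negbin", outcome="y", exposure="x", offset="py", fix_sigma=0.0
            ),
            df,
        )
        oracle = sm.NegativeBinomial(
            y, sm.add_constant(x), offset=np.log(py)
        ).fit(method="newton", tol=1e-10, maxiter=500, disp=0)
        np.testing.assert_allclose(fit.beta, np.asarray(oracle.params)[:2], atol=1e-6)
        assert fit.alpha == pytest.approx(np.asarray(oracle.params)[2], abs=1e-5)

    def test_negbin_poisson_limit(self):
        # Poisson-generated counts: alpha -> 0 and coefficients match Poisson ML
        rng = np.random.default_rng(3)
        n = 1500
        x = rng.normal(0, 1, n)
        y = rng.poisson(np.exp(0.4 + 0.3 * x))
        df = pd.DataFrame({"y": y, "x": x, "county": rng.integers(0, 4, n)})
        fit = fit_glmm(
            ModelSpec(family="negbin", outcome="y", exposure="x", fix_sigma=0.0), df
        )
        oracle = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-3)
        assert fit.alpha < 0.1  # at the boundary up to sampling noise


def _dense_loglik(beta, sigma, y, X, g, family="logistic", alpha=None, offset=None):
    """Brute-force trapezoid integration over the random intercept."""
    f = X @ beta + (offset if offset is not None else 0.0)
    us = np.linspace(-12 * sigma, 12 * sigma, 10001)
    total = 0.0
    for grp in np.unique(g):
        m = g == grp
        eta = f[m][:, None] + us[None, :]
        if family == "logistic":
            ll = (y[m][:, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
        else:
            from scipy.special import gammaln

            mu = np.exp(eta)
            a = alpha
            ll = (
                gammaln(y[m][:, None] + 1 / a)
                - gammaln(1 / a)
                - gammaln(y[m][:, None] + 1)
                + y[m][:, None] * np.log(a)
                + y[m][:, None] * eta
                - (y[m][:, None] + 1 / a) * np.log1p(a * mu)
            ).sum(axis=0)
        prior = -0.5 * np.log(2 * np.pi) - np.log(sigma) - us**2 / (2 * sigma**2)
        total += np.log(np.trapezoid(np.exp(ll + prior), us))
    return total


class TestQuadratureOracle:
    @pytest.mark.parametrize("seed,sigma", [(1, 0.3), (2, 0.8), (3, 1.5)])
    def test_logistic_agq_matches_dense(self, seed, sigma):
        df = simulate_logistic(400, 8, (-0.5, 0.8), sigma, seed=seed)
        y = df["y"].to_numpy()
        X = np.column_stack([np.ones(len(df)), df["x"]])
        g = df["county"].to_numpy()
        beta = np.array([-0.4, 0.7])
        ll = marginal_loglik(beta, sigma, y, X, g, "logistic", n_quad=15)
        dense = _dense_loglik(beta, sigma, y, X, g)
        assert ll == pytest.approx(dense, rel=1e-6)

    def test_negbin_agq_matches_dense(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(0, 1, n)
        g = rng.integers(0, 6, n)
        u = rng.normal(0, 0.5, 6)
        mu = np.exp(0.3 + 0.4 * x + u[g])
        y = rng.poisson(rng.gamma(1 / 0.7, 0.7 * mu)).astype(float)
        X = np.column_stack([np.ones(n), x])
        beta = np.array([0.2, 0.3])
        ll = marginal_loglik(beta, 0.6, y, X, g, "negbin", alpha=0.7, n_quad=15)
        dense = _dense_loglik(beta, 0.6, y, X, g, "negbin", alpha=0.7)
        assert ll == pytest.approx(dense, rel=1e-6)


class TestMixedFit:
    def test_parameter_recovery_moderate_n(self):
        df = simulate_logistic(6000, 12, (-1.0, np.log(1.5)), 0.3, seed=4)
        fit = fit_glmm(ModelSpec(family="logistic", outcome="y", exposure="x"), df)
        b = fit.coef("x")
        s = fit.se[fit.names.index("x")]
        assert fit.converged
        assert b - 1.96 * s < np.log(1.5) < b + 1.96 * s
        assert 0.1 < fit.sigma_u < 0.7

    def test_covariate_shift_changes_only_intercept(self):
        df = simulate_logistic(2000, 6, (-0.5, 0.4), 0.3, seed=5)
        df["z"] = np.random.default_rng(6).normal(0, 1, len(df))
        spec = ModelSpec(
            family="logistic", outcome="y", exposure="x", covariates=("z",)
        )
        fit1 = fit_glmm(spec, df)
        df2 = df.copy()
        df2["z"] = df2["z"] + 10.0
        fit2 = fit_glmm(spec, df2)
        i = fit1.names.index("z")
        assert fit2.beta[i] == pytest.approx(fit1.beta[i], abs=5e-4)
        assert fit2.coef("x") == pytest.approx(fit1.coef("x"), abs=5e-4)
        # intercept absorbs the shift exactly: b0' = b0 - c * b_z
        assert fit2.beta[0] == pytest.approx(
            fit1.beta[0] - 10.0 * fit1.beta[i], abs=5e-3
        )

    def test_singular_design_names_columns(self):
        df = simulate_logistic(200, 4, (0.0, 0.3), 0.2, seed=7)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="x2|x"):
            fit_glmm(
                ModelSpec(
                    family="logistic", outcome="y", exposure="x", covariates=("x2",)
                ),
                df,
            )

    def test_single_group_rejected_with_random_intercept(self):
        df = simulate_logistic(100, 1, (0.0, 0.3), 0.0, seed=8)
        with pytest.raises(ValueError, match="2 groups"):
            fit_glmm(ModelSpec(family="logistic", outcome="y", exposure="x"), df)

    def test_offset_only_for_negbin(self):
        with pytest.raises(ValueError):
            ModelSpec(family="logistic", outcome="y", exposure="x", offset="py")


class TestEffectTable:
    def fit(self):
        return fit_glmm(
            ModelSpec(family="logistic", outcome="y", exposure="x", fix_sigma=0.0),
            two_by_two(50, 50, 50, 50),
        )

    def test_null_effect_is_one(self):
        tab = glmm.effect_table([self.fit()])
        assert tab["estimate"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_wald_ci_definition(self):
        fit = self.fit()
        tab = glmm.effect_table([fit])
        b = tab["beta"].iloc[0]
        s = tab["se"].iloc[0]
        z = 1.959963984540054
        assert tab["lower"].iloc[0] == pytest.approx(np.exp(b - z * s), rel=1e-12)
        assert tab["upper"].iloc[0] == pytest.approx(np.exp(b + z * s), rel=1e-12)
        assert tab["lower"].iloc[0] <= tab["estimate"].iloc[0] <= tab["upper"].iloc[0]

    def test_empty_list_gives_header_only(self):
        tab = glmm.effect_table([])
        assert len(tab) == 0
        assert "estimate" in tab.columns and "outcome" in tab.columns

    def test_six_sig_digit_roundtrip(self, tmp_path):
        tab = glmm.effect_table([self.fit()])
        p = tmp_path / "t.csv"
        tab.to_csv(p, index=False, float_format="%.6g")
        back = pd.read_csv(p)
        for col in ("estimate", "lower", "upper"):
            assert back[col].iloc[0] == pytest.approx(tab[col].iloc[0], rel=1e-5)


def test_deviance_residuals_shapes_and_sign(analysis_frame):
    spec = ModelSpec(
        family="logistic",
        outcome="case",
        exposure="no2_per5",
        covariates=("age_cat", "sex"),
    )
    fit = fit_glmm(spec, analysis_frame)
    resid = glmm.deviance_residuals(fit, analysis_frame)
    assert resid.shape == (len(analysis_frame),)
    assert np.all(np.isfinite(resid))
    y = analysis_frame["case"].to_numpy()
    assert np.all(resid[y == 1] >= 0) and np.all(resid[y == 0] <= 0)
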