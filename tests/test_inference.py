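"""Tests for the random-intercept logistic model, LRT, and curve summaries."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate

from boosterdd import (
    DegenerateInputError,
    DiscountProfile,
    DomainError,
    IndifferencePoint,
    UsageError,
    fit_glmm,
    glmm_loglik,
    group_curves,
    lrt,
    scale_predictors,
)
from boosterdd.titration import DEFAULT_DELAYS


def toy_glmm_data(seed=3, n=12, n_groups=2):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n).astype(float)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    g = np.repeat(np.arange(n_groups), n // n_groups)
    return y, X, g


def dense_loglik_oracle(y, X, g, beta, sigma):
    """Brute-force numerical integration over each group's intercept."""
    total = 0.0
    for grp in np.unique(g):
        idx = g == grp

        def f(u):
            eta = X[idx] @ beta + u
            cond = np.sum(y[idx] * eta - np.logaddexp(0, eta))
            return np.exp(cond) * np.exp(-(u**2) / (2 * sigma**2)) / np.sqrt(2 * np.pi * sigma**2)

        val, _ = integrate.quad(f, -12 * sigma, 12 * sigma, limit=400)
        total += np.log(val)
    return total


class TestScalePredictors:
    def test_hand_computed_z_scores(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 6.0], "b": [1.0, 1.0, 1.0]})
        out = scale_predictors(df, ["a"])
        sd = np.std([1, 2, 6], ddof=1)
        assert out["a"].tolist() == pytest.approx([(1 - 3) / sd, (2 - 3) / sd, (6 - 3) / sd])
        assert out["b"].tolist() == [1.0, 1.0, 1.0]  # untouched
        assert out.attrs["scaling"]["a"] == pytest.approx((3.0, sd))

    def test_already_standard_column_unchanged(self, rng):
        v = rng.normal(size=200)
        v = (v - v.mean()) / v.std(ddof=1)
        out = scale_predictors(pd.DataFrame({"a": v}), ["a"])
        assert out["a"].to_numpy() == pytest.approx(v, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            scale_predictors(pd.DataFrame({"a": [2.0, 2.0, 2.0]}), ["a"])


class TestMarginalLikelihood:
    def test_matches_dense_integration_on_toy_data(self):
        y, X, g = toy_glmm_data()
        beta = np.array([0.3, -0.5])
        for sigma in [0.3, 0.8, 1.5]:
            agq = glmm_loglik(y, X, g, beta, sigma, n_nodes=25)
            oracle = dense_loglik_oracle(y, X, g, beta, sigma)
            assert agq == pytest.approx(oracle, abs=1e-9)

    def test_quadrature_refinement_approaches_oracle(self):
        y, X, g = toy_glmm_data()
        beta = np.array([0.3, -0.5])
        oracle = dense_loglik_oracle(y, X, g, beta, 0.8)
        errs = [abs(glmm_loglik(y, X, g, beta, 0.8, n_nodes=k) - oracle) for k in (1, 3, 5, 9, 15)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-9

    def test_sigma_zero_is_plain_bernoulli(self):
        y, X, g = toy_glmm_data()
        beta = np.array([0.2, 0.4])
        eta = X @ beta
        expected = np.sum(y * eta - np.logaddexp(0, eta))
        assert glmm_loglik(y, X, g, beta, 0.0) == pytest.approx(expected)


class TestFitGlmm:
    def test_zero_group_variance_matches_logit_oracle(self):
        rng = np.random.default_rng(11)
        n = 3000
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        eta = 0.5 + 0.8 * x1 - 0.4 * x2
        df = pd.DataFrame(
            {
                "y": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int),
                "x1": x1,
                "x2": x2,
                "country": rng.integers(0, 13, n),
            }
        )
        fit = fit_glmm(df, "y ~ x1 + x2", group="country")
        oracle = sm.Logit(df["y"], sm.add_constant(df[["x1", "x2"]])).fit(disp=0)
        assert fit.intercept_sd == pytest.approx(0.0, abs=1e-3)
        assert fit.params["b"].to_numpy() == pytest.approx(oracle.params.to_numpy(), abs=1e-4)

    def test_matches_lme4_glmer_on_grouped_data(self, tmp_path):
        """Independent oracle: lme4::glmer with matched quadrature."""
        rng = np.random.default_rng(5)
        n, G = 400, 6
        g = rng.integers(0, G, n)
        u = rng.normal(0, 0.6, G)
        x1 = rng.normal(size=n)
        eta = 0.2 + 0.9 * x1 + u[g]
        df = pd.DataFrame(
            {"y": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int), "x1": x1, "country": g}
        )
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- glmer(y ~ x1 + (1|country), data=d, family=binomial, nAGQ=25)
            cat(sprintf('%.10f\\n', c(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)))))
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, sigma_r, ll_r = [float(v) for v in out.stdout.split()]
        fit = fit_glmm(df, "y ~ x1", group="country", n_nodes=25)
        assert fit.params.loc["intercept", "b"] == pytest.approx(b0, abs=1e-3)
        assert fit.params.loc["x1", "b"] == pytest.approx(b1, abs=1e-3)
        assert fit.intercept_sd == pytest.approx(sigma_r, abs=1e-3)
        assert fit.loglik == pytest.approx(ll_r, abs=1e-3)

    def test_or_and_ci_are_pure_transforms(self):
        y, X, g = toy_glmm_data(n=60, n_groups=3)
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "country": g})
        fit = fit_glmm(df, "y ~ x1", group="country")
        assert np.allclose(fit.params["or"], np.exp(fit.params["b"]))
        assert np.allclose(fit.params["ci_low"], np.exp(fit.params["b"] - 1.96 * fit.params["se"]))
        assert np.allclose(fit.params["ci_high"], np.exp(fit.params["b"] + 1.96 * fit.params["se"]))
        assert (fit.params["ci_low"] <= fit.params["or"]).all()
        assert (fit.params["or"] <= fit.params["ci_high"]).all()

    def test_listwise_deletion_and_binary_check(self):
        df = pd.DataFrame(
            {
                "y": [0, 1, 1, np.nan, 0, 1, 0, 1],
                "x1": [0.1, 0.3, np.nan, 0.2, -1.0, 0.5, 0.7, -0.2],
                "country": list("aabbccdd"),
            }
        )
        fit = fit_glmm(df, "y ~ x1")
        assert fit.n_obs == 6
        with pytest.raises(DomainError):
            fit_glmm(pd.DataFrame({"y": [1, 2, 1, 2], "x1": [0.0, 1, 2, 3],
                                   "country": list("aabb")}), "y ~ x1")


class TestLrt:
    def _fits(self):
        rng = np.random.default_rng(21)
        n = 500
        g = rng.integers(0, 5, n)
        x = rng.normal(size=n)
        eta = 0.3 + 0.7 * x + rng.normal(0, 0.4, 5)[g]
        df = pd.DataFrame(
            {"y": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int), "x1": x, "country": g}
        )
        full = fit_glmm(df, "y ~ x1")
        null = fit_glmm(df, "y ~ 1")
        return full, null

    def test_statistic_matches_loglik_arithmetic(self):
        full, null = self._fits()
        res = lrt(full, null)
        assert res.statistic == pytest.approx(2 * (full.loglik - null.loglik))
        assert res.df == 1
        from scipy import stats as sps

        assert res.p == pytest.approx(sps.chi2.sf(res.statistic, 1))

    def test_identical_models_statistic_zero(self):
        full, _ = self._fits()
        res = lrt(full, full)
        assert res.statistic == 0.0 and res.df == 0 and res.p == 1.0

    def test_row_mismatch_rejected(self):
        full, null = self._fits()
        object.__setattr__(null, "n_obs", null.n_obs - 1)
        with pytest.raises(UsageError):
            lrt(full, null)


class TestGroupCurves:
    def _profile(self, values):
        pts = tuple(IndifferencePoint(d, v) for d, v in zip(DEFAULT_DELAYS, values))
        return DiscountProfile(points=pts, delayed_amount=2000.0)

    def test_identical_groups_identical_curves(self):
        profiles = [self._profile([1000.0] * 7)] * 6
        curves = group_curves(profiles, [0, 0, 0, 1, 1, 1])
        wide = curves.pivot(index="delay_days", columns="group", values="mean")
        assert (wide[0] == wide[1]).all()

    def test_low_k_group_dominates_pointwise(self):
        shallow = [self._profile([1900 - 10 * i for i in range(7)]) for _ in range(5)]
        steep = [self._profile([1500 - 150 * i for i in range(7)]) for _ in range(5)]
        curves = group_curves(shallow + steep, [1] * 5 + [0] * 5)
        wide = curves.pivot(index="delay_days", columns="group", values="mean")
        assert (wide[1] > wide[0]).all()

    def test_se_matches_textbook_formula(self):
        vals = [[1000.0] * 7, [1200.0] * 7, [1400.0] * 7]
        profiles = [self._profile(v) for v in vals]
        curves = group_curves(profiles, [0, 0, 0])
        expected_se = np.std([1000, 1200, 1400], ddof=1) / np.sqrt(3)
        assert curves["se"].to_numpy() == pytest.approx(np.full(7, expected_se))

    def test_empty_group_rejected(self):
        with pytest.raises(UsageError):
            group_curves([self._profile([1000.0] * 7)], [0, 1])
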