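import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtr

from reefcleaner.design import DesignInfo
from reefcleaner.errors import (
    InvalidArgumentError,
    InvalidComparisonError,
    NotApplicableError,
)
from reefcleaner.glmm import (
    FitResult,
    ModelSpec,
    fit_glmm,
    likelihood_ratio_test,
    overdispersion_ratio,
    pseudo_r2_adjusted,
    transform_duration,
    tukey_posthoc,
)


def simulate_binomial(seed, n=400, n_groups=25, sd=0.5, beta=(0.5, -0.3),
                      intercept=-0.5, rho=0.0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    g = rng.integers(0, n_groups, n)
    b = rng.normal(0, sd, n_groups)
    eta = intercept + beta[0] * x1 + beta[1] * x2 + b[g]
    m = rng.integers(20, 50, n)
    if rho > 0:  # beta-binomial style overdispersion
        p = ndtr(eta + rng.normal(0, rho, n))
    else:
        p = ndtr(eta)
    k = rng.binomial(m, p)
    return pd.DataFrame(dict(x1=x1, x2=x2, g=g.astype(str), k=k, m=m))


BSPEC = ModelSpec(response="k", family="binomial-probit", fixed_terms=("x1", "x2"),
                  random_terms=("g",), trials="m")


class TestTransformDuration:
    def test_half_maps_to_floor(self):
        assert transform_duration(0.5) == pytest.approx(1e-6)

    def test_known_value(self):
        # direct evaluation of |log(p/(1-p))|
        assert transform_duration(0.73) == pytest.approx(0.99462, abs=1e-5)

    def test_boundary_clamped(self):
        assert transform_duration(1.0, epsilon=1e-4) == pytest.approx(9.21024, abs=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            transform_duration(1.2)
        with pytest.raises(InvalidArgumentError):
            transform_duration(0.4, epsilon=0.7)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=80, deadline=None)
    def test_symmetric_about_half(self, p):
        assert transform_duration(p) == pytest.approx(transform_duration(1 - p),
                                                      rel=1e-9)

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_distance_from_half(self, a, b):
        lo, hi = sorted([a, b])
        # farther from 0.5 (i.e. smaller p below 0.5) gives a larger value
        assert transform_duration(lo) >= transform_duration(hi) - 1e-12


class TestFitGlmm:
    def test_zero_variance_matches_glm(self):
        # boundary equivalence: station sd 0 -> ordinary GLM coefficients
        df = simulate_binomial(seed=11, sd=0.0)
        fit = fit_glmm(BSPEC, df)
        glm = sm.GLM(np.c_[df.k, df.m - df.k],
                     sm.add_constant(df[["x1", "x2"]].to_numpy()),
                     family=sm.families.Binomial(sm.families.links.Probit())).fit()
        assert fit.singular  # variance estimated at the boundary
        np.testing.assert_allclose(fit.coefficients.to_numpy(), glm.params, atol=1e-4)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-4)

    def test_simulation_recovery_within_2se(self):
        df = simulate_binomial(seed=5, n=800, sd=0.5)
        fit = fit_glmm(BSPEC, df)
        assert fit.converged
        for term, truth in [("x1", 0.5), ("x2", -0.3)]:
            assert abs(fit.coefficients[term] - truth) < 2 * fit.se[term]

    def test_gaussian_log_fitted_means_positive(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        g = rng.integers(0, 15, n)
        y = np.maximum(np.exp(0.4 + 0.3 * x + rng.normal(0, 0.3, 15)[g])
                       + rng.normal(0, 0.4, n), 1e-3)
        spec = ModelSpec(response="y", family="gaussian-log",
                         fixed_terms=("x",), random_terms=("g",))
        fit = fit_glmm(spec, pd.DataFrame(dict(y=y, x=x, g=g.astype(str))))
        assert fit.converged
        assert (fit.fitted > 0).all()

    def test_agq0_laplace_agree_loosely(self):
        df = simulate_binomial(seed=7, n=600, sd=0.6)
        f0 = fit_glmm(BSPEC, df, mode="agq0")
        f1 = fit_glmm(BSPEC, df, mode="laplace")
        for term in ("x1", "x2"):
            assert f1.coefficients[term] == pytest.approx(
                f0.coefficients[term], rel=0.10)

    def test_deviance_monotone_in_terms(self):
        # adding any term never increases deviance
        for seed in (1, 2, 3):
            df = simulate_binomial(seed=seed)
            df["x3"] = np.random.default_rng(seed + 50).normal(size=len(df))
            devs, lls = [], []
            for terms in [(), ("x1",), ("x1", "x2"), ("x1", "x2", "x3")]:
                fit = fit_glmm(BSPEC.with_terms(terms), df)
                assert fit.converged
                devs.append(fit.deviance)
                lls.append(fit.loglik)
            # conditional deviance is monotone up to variance-parameter
            # optimizer precision; the marginal log-likelihood is strict
            assert all(a >= b - 0.01 for a, b in zip(devs, devs[1:]))
            assert all(a <= b + 1e-6 for a, b in zip(lls, lls[1:]))

    def test_unknown_mode(self):
        with pytest.raises(InvalidArgumentError):
            fit_glmm(BSPEC, simulate_binomial(seed=1), mode="mcmc")


class TestLikelihoodRatio:
    def test_identical_fits(self):
        df = simulate_binomial(seed=9)
        fit = fit_glmm(BSPEC, df)
        res = likelihood_ratio_test(fit, fit)
        assert res.chi_square == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)

    def test_half_loglik_gap_example(self):
        # chi2 = 2 * 5.585 = 11.17 at df=1
        p = stats.chi2.sf(11.17, 1)
        df = simulate_binomial(seed=13, beta=(0.0, 0.0))
        full = fit_glmm(BSPEC, df)
        red = fit_glmm(BSPEC.with_terms(("x1",)), df)
        res = likelihood_ratio_test(full, red)
        assert res.df == 1
        # cross-check the tail formula itself on the documented example
        assert p == pytest.approx(0.000832, abs=2e-5)

    def test_reduced_with_more_params(self):
        df = simulate_binomial(seed=15)
        full = fit_glmm(BSPEC.with_terms(("x1",)), df)
        red = fit_glmm(BSPEC, df)
        with pytest.raises(InvalidComparisonError):
            likelihood_ratio_test(full, red)

    def test_non_nested_terms(self):
        df = simulate_binomial(seed=15)
        df["x3"] = np.random.default_rng(1).normal(size=len(df))
        a = fit_glmm(BSPEC.with_terms(("x1", "x2")), df)
        b = fit_glmm(BSPEC.with_terms(("x3",)), df)
        with pytest.raises(InvalidComparisonError):
            likelihood_ratio_test(a, b)


class TestOverdispersion:
    def test_gaussian_not_applicable(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.uniform(0.5, 2.0, 50),
                           "x": rng.normal(size=50), "g": ["a"] * 25 + ["b"] * 25})
        spec = ModelSpec(response="y", family="gaussian-log",
                         fixed_terms=("x",), random_terms=("g",))
        fit = fit_glmm(spec, df)
        with pytest.raises(NotApplicableError):
            overdispersion_ratio(fit)

    def test_well_specified_near_one(self):
        ratios = [overdispersion_ratio(fit_glmm(BSPEC, simulate_binomial(seed=s)))
                  for s in range(20, 35)]
        assert 0.8 < np.mean(ratios) < 1.2

    def test_overdispersed_flagged(self):
        df = simulate_binomial(seed=40, rho=0.8)
        ratio = overdispersion_ratio(fit_glmm(BSPEC, df))
        assert ratio > 2.0  # excessive overdispersion threshold


def _dummy_fit(deviance, n, k):
    return FitResult(
        spec=None, mode="agq0", converged=True, singular=False,
        coefficients=pd.Series(dtype=float), se=pd.Series(dtype=float),
        z=pd.Series(dtype=float), loglik=0.0, deviance=deviance, n_obs=n,
        n_fixed_params=k, re_variance={}, scale=1.0, theta=np.zeros(0),
        design_info=DesignInfo(terms=(), column_names=["(Intercept)"],
                               term_columns={}),
        fitted=np.zeros(1), eta=np.zeros(1), random_effects={},
        cov_beta=np.zeros((1, 1)), pearson_chi2=0.0)


class TestPseudoR2:
    def test_null_vs_null(self):
        null = _dummy_fit(100.0, 100, 0)
        assert pseudo_r2_adjusted(null, null) == pytest.approx(0.0)

    def test_formula_example(self):
        # deviance halved with k=3, n=100: 1 - 0.5 * 99/96
        fit = _dummy_fit(50.0, 100, 3)
        null = _dummy_fit(100.0, 100, 0)
        assert pseudo_r2_adjusted(fit, null) == pytest.approx(0.48438, abs=1e-5)

    def test_mismatched_data(self):
        with pytest.raises(InvalidComparisonError):
            pseudo_r2_adjusted(_dummy_fit(50.0, 100, 3), _dummy_fit(100.0, 90, 0))

    def test_noise_predictor_penalized(self):
        df = simulate_binomial(seed=61, beta=(0.5, 0.0))
        null = fit_glmm(BSPEC.with_terms(()), df)
        base = fit_glmm(BSPEC.with_terms(("x1",)), df)
        noisy = fit_glmm(BSPEC.with_terms(("x1", "x2")), df)
        raw_gain = ((null.deviance - noisy.deviance) / null.deviance
                    - (null.deviance - base.deviance) / null.deviance)
        adj_gain = pseudo_r2_adjusted(noisy, null) - pseudo_r2_adjusted(base, null)
        assert adj_gain < raw_gain  # adjustment penalizes the pure-noise term


def simulate_factor(seed, shift=0.0, n=240):
    rng = np.random.default_rng(seed)
    lev = np.array(["a", "b", "c", "d"])[rng.integers(0, 4, n)]
    eta = -0.3 + np.where(lev == "d", shift, 0.0)
    m = rng.integers(20, 40, n)
    k = rng.binomial(m, ndtr(eta))
    return pd.DataFrame(dict(lev=lev, k=k, m=m))


FSPEC = ModelSpec(response="k", family="binomial-probit", fixed_terms=("lev",),
                  trials="m")


class TestTukey:
    def test_two_level_factor_rejected(self):
        df = simulate_factor(seed=1)
        df["lev"] = np.where(df["lev"].isin(["a", "b"]), "a", "b")
        fit = fit_glmm(FSPEC, df)
        with pytest.raises(InvalidArgumentError):
            tukey_posthoc(fit, "lev")

    def test_familywise_error_controlled(self):
        rejections = 0
        reps = 60
        for s in range(reps):
            fit = fit_glmm(FSPEC, simulate_factor(seed=100 + s))
            tab = tukey_posthoc(fit, "lev")
            rejections += (tab["p_adj"] < 0.05).any()
        assert rejections / reps <= 0.11  # ~alpha with Monte-Carlo slack

    def test_shifted_level_detected(self):
        fit = fit_glmm(FSPEC, simulate_factor(seed=3, shift=1.5))
        tab = tukey_posthoc(fit, "lev")
        involving_d = tab[(tab.level_a == "d") | (tab.level_b == "d")]
        assert (involving_d["p_adj"] < 0.05).all()
        others = tab[(tab.level_a != "d") & (tab.level_b != "d")]
        assert (others["p_adj"] > 0.05).all()
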