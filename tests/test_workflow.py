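import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from statsmodels.stats.outliers_influence import variance_inflation_factor

from reefcleaner.errors import InvalidArgumentError
from reefcleaner.glmm import ModelSpec, fit_glmm
from reefcleaner.workflow import (
    backward_stepwise,
    forward_check,
    importance_added_last,
    observer_sensitivity,
    temporal_models,
    vif_screen,
    within_year_nested,
)


def simulate(seed, beta=(0.6, -0.6, 0.0), n=500, sd=0.3, year_shift=0.0,
             tod_slope_years=(), years=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    g = rng.integers(0, 20, n)
    b = rng.normal(0, sd, 20)
    year = rng.integers(0, years, n)
    tod = rng.uniform(7.5, 17.0, n)
    todz = (tod - tod.mean()) / tod.std()
    eta = -0.5 + X @ np.array(beta) + b[g]
    eta = eta + np.where(year == years - 1, year_shift, 0.0)
    for t in tod_slope_years:
        eta = eta + np.where(year == t, -0.5 * todz, 0.0)
    m = rng.integers(15, 40, n)
    k = rng.binomial(m, ndtr(eta))
    obs = rng.random(n) < 0.5
    return pd.DataFrame({
        "x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2], "g": g.astype(str),
        "year": np.array([f"y{t}" for t in year]), "time_of_day": todz,
        "observer_type": np.where(obs, "multi-year", "single-year"),
        "k": k, "m": m})


SPEC = ModelSpec(response="k", family="binomial-probit",
                 fixed_terms=("x1", "x2", "x3"), random_terms=("g",), trials="m")


class TestBackwardStepwise:
    def test_strong_terms_no_deletion(self):
        df = simulate(seed=1, beta=(0.8, -0.8, 0.7))
        trace = backward_stepwise(SPEC, df)
        assert [s for s in trace.steps if s.action == "drop"] == []
        assert set(trace.final_spec.fixed_terms) == {"x1", "x2", "x3"}

    def test_noise_term_deleted(self):
        dropped = 0
        for s in range(8):
            trace = backward_stepwise(SPEC, simulate(seed=40 + s))
            dropped += "x3" not in trace.final_spec.fixed_terms
        assert dropped >= 6  # pure-noise term removed in most replicates

    def test_intercept_only_candidates(self):
        df = simulate(seed=2)
        trace = backward_stepwise(SPEC.with_terms(()), df)
        assert trace.final_spec.fixed_terms == ()
        assert [s for s in trace.steps if s.action == "drop"] == []

    def test_no_term_above_alpha_retained(self):
        for s in (3, 4, 5):
            df = simulate(seed=s)
            trace = backward_stepwise(SPEC, df)
            fit = trace.final_fit
            for term in trace.final_spec.fixed_terms:
                red = fit_glmm(trace.final_spec.drop_term(term), df)
                from reefcleaner.glmm import likelihood_ratio_test

                assert likelihood_ratio_test(fit, red).p_value < 0.05

    def test_protected_term_kept(self):
        df = simulate(seed=6)
        trace = backward_stepwise(SPEC.add_term("observer_type"), df,
                                  protected=("observer_type",))
        assert "observer_type" in trace.final_spec.fixed_terms

    def test_log_lines_parseable(self):
        trace = backward_stepwise(SPEC, simulate(seed=7))
        for line in trace.log_lines():
            assert len(line.split("\t")) == 6


class TestForwardCheck:
    def test_orthogonal_predictors_agree(self):
        df = simulate(seed=8, beta=(0.8, -0.8, 0.0))
        trace = backward_stepwise(SPEC, df)
        assert forward_check(trace, SPEC, df) is True
        assert trace.forward_agreement is True

    def test_single_predictor_trivial(self):
        df = simulate(seed=9, beta=(0.8, 0.0, 0.0))
        spec = SPEC.with_terms(("x1",))
        trace = backward_stepwise(spec, df)
        assert forward_check(trace, spec, df) is True

    def test_collinear_disagreement_is_reported_not_raised(self):
        rng = np.random.default_rng(10)
        n = 400
        x1 = rng.normal(size=n)
        x2 = 0.95 * x1 + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=n)
        g = rng.integers(0, 10, n)
        m = rng.integers(15, 30, n)
        k = rng.binomial(m, ndtr(-0.3 + 0.25 * x1 + 0.25 * x2))
        df = pd.DataFrame(dict(x1=x1, x2=x2, x3=rng.normal(size=n),
                               g=g.astype(str), k=k, m=m))
        trace = backward_stepwise(SPEC, df)
        flag = forward_check(trace, SPEC, df)
        assert flag in (True, False)  # valid outcome either way


class TestVif:
    def test_orthogonal_columns(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(200, 3))
        base -= base.mean(axis=0)          # centred span stays centred under QR
        q, _ = np.linalg.qr(base)
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        out = vif_screen(df, ["a", "b", "c"])
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        out = vif_screen(pd.DataFrame({"a": x, "b": x}), ["a", "b"])
        assert np.isinf(out["vif"]).all()
        assert out["flagged"].all()

    def test_closed_form_correlation_08(self):
        # construct exactly r = 0.8 -> VIF = 1/(1-0.64) = 2.78
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=300)
        e -= e.mean()
        e -= x * (x @ e) / (x @ x)  # orthogonalize exactly (x is centred)
        e /= e.std()
        y = 0.8 * x + 0.6 * e
        out = vif_screen(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        np.testing.assert_allclose(out["vif"], 1.0 / (1.0 - 0.64), rtol=1e-6)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 3))
        X[:, 2] += 0.5 * X[:, 0]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        ours = vif_screen(df, ["a", "b", "c"])["vif"].to_numpy()
        Xc = np.column_stack([np.ones(150), X - X.mean(axis=0)])
        theirs = [variance_inflation_factor(Xc, j + 1) for j in range(3)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)

    def test_needs_two_terms(self):
        with pytest.raises(InvalidArgumentError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


class TestImportance:
    def test_single_predictor_delta_equals_total(self):
        df = simulate(seed=11, beta=(0.8, 0.0, 0.0))
        spec = SPEC.with_terms(("x1",))
        imp = importance_added_last(spec, df)
        assert imp.table.loc[0, "delta_r2"] == pytest.approx(imp.final_r2, abs=1e-9)

    def test_dominant_predictor_ranks_first(self):
        wins = 0
        for s in range(6):
            df = simulate(seed=60 + s, beta=(1.0, 0.1, 0.0))
            imp = importance_added_last(SPEC.with_terms(("x1", "x2")), df)
            wins += imp.most_important == "x1"
        assert wins >= 5

    def test_order_invariance(self):
        df = simulate(seed=12, beta=(0.6, -0.6, 0.3))
        a = importance_added_last(SPEC.with_terms(("x1", "x2", "x3")), df)
        b = importance_added_last(SPEC.with_terms(("x3", "x1", "x2")), df)
        ta = a.table.set_index("term")["delta_r2"]
        tb = b.table.set_index("term")["delta_r2"]
        for term in ("x1", "x2", "x3"):
            assert ta[term] == pytest.approx(tb[term], abs=1e-6)

    def test_null_predictor_near_zero(self):
        df = simulate(seed=13, beta=(0.8, 0.0, 0.0))
        imp = importance_added_last(SPEC.with_terms(("x1", "x3")), df)
        row = imp.table.set_index("term")
        assert abs(row.loc["x3", "delta_r2"]) < 0.05

    def test_group_mean_weighting_identity(self, freq_model):
        # mean over all factor delta-R2 equals the 3/4/5-weighted group mean
        data, spec = freq_model
        from reefcleaner.synth import ALL_FACTORS

        imp = importance_added_last(spec.with_terms(ALL_FACTORS), data)
        tab = imp.table.dropna(subset=["group"])
        overall = tab["delta_r2"].mean()
        weights = tab.groupby("group").size()
        weighted = (imp.group_means * weights).sum() / weights.sum()
        assert overall == pytest.approx(weighted, abs=1e-12)
        assert sorted(weights) == [3, 4, 5]


class TestTemporal:
    def test_year_shift_detected_with_tukey(self):
        df = simulate(seed=14, beta=(0, 0, 0), year_shift=0.8)
        spec = SPEC.with_terms(("year", "time_of_day"))
        res = temporal_models(spec, df)
        assert res.year_lrt.p_value < 0.001
        shifted = res.year_tukey[(res.year_tukey.level_a == "y3")
                                 | (res.year_tukey.level_b == "y3")]
        assert (shifted["p_adj"] < 0.05).any()

    def test_null_year_not_rejected_seeded(self):
        df = simulate(seed=15, beta=(0, 0, 0))
        res = temporal_models(SPEC.with_terms(("year", "time_of_day")), df)
        assert res.year_lrt.p_value > 0.05

    def test_nested_time_of_day_per_year(self):
        df = simulate(seed=16, beta=(0, 0, 0), tod_slope_years=(0, 1), n=900)
        res = temporal_models(SPEC.with_terms(("year", "time_of_day")), df)
        nz = res.nested_time_z.set_index("year")
        assert (nz.loc[["y0", "y1"], "p"] < 0.05).all()
        assert (nz.loc[["y2", "y3"], "p"] > 0.01).all()

    def test_single_year_skipped(self):
        df = simulate(seed=17, beta=(0, 0, 0))
        df["year"] = "y0"
        res = temporal_models(SPEC.with_terms(("year", "time_of_day")), df)
        assert res.year_lrt is None
        assert any("single year" in n for n in res.notes)


class TestWithinYear:
    def test_year_constant_effect_mostly_significant(self):
        df = simulate(seed=18, beta=(0.8, 0.0, 0.0), n=800)
        spec = SPEC.with_terms(("x1",))
        tab = within_year_nested("x1", spec, df)
        assert tab.attrs["n_years"] == 4
        assert tab.attrs["n_significant"] >= 3

    def test_constant_within_year_reported_na(self):
        df = simulate(seed=19)
        df.loc[df.year == "y0", "x1"] = 2.0  # no variation in year y0
        tab = within_year_nested("x1", SPEC.with_terms(("x1",)), df)
        row = tab.set_index("year").loc["y0"]
        assert np.isnan(row["p"])
        assert row["significant"] is pd.NA

    def test_categorical_predictor_subset_lrt(self):
        df = simulate(seed=20)
        df["lev"] = np.where(df.x1 > 0, "hi", "lo")
        spec = SPEC.with_terms(("lev",))
        tab = within_year_nested("lev", spec, df)
        assert set(tab.columns) >= {"year", "chi_square", "p", "significant"}
        assert len(tab) == 4

    def test_predictor_not_in_model(self):
        with pytest.raises(InvalidArgumentError):
            within_year_nested("x9", SPEC, simulate(seed=21))


class TestObserverSensitivity:
    def test_no_observer_column_skipped(self):
        df = simulate(seed=22).drop(columns="observer_type")
        flag, table = observer_sensitivity(SPEC, df)
        assert flag is None and table.empty

    def test_null_observer_flag_true(self):
        df = simulate(seed=23, beta=(0.8, -0.8, 0.0))
        spec = SPEC.with_terms(("x1", "x2", "observer_type"))
        flag, table = observer_sensitivity(spec, df)
        assert flag is True
        assert set(table["term"]) == {"x1", "x2"}
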