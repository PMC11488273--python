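"""Preprocessing, contrast coding, and the two mixed-model fitters."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from edhloc.errors import DegenerateDataError, ValidationError
from edhloc.mixed_models import (ModelSpec, bonferroni, build_design,
                                 fit_lmm, fit_lmm_ml, fit_nb_glmm,
                                 missingness_diagnostics, nb_laplace_loglik,
                                 partial_r2, preprocess, profiled_deviance,
                                 region_dummies, simple_code)
from helpers import agq_loglik, simulate_lmm


def _toy_long(n_participants=4, episodes=(1,)):
    rows = []
    for i in range(n_participants):
        for ep in episodes:
            for tp, day in [("admission", 0), ("stepdown", 30), ("discharge", 80)]:
                rows.append({"participant_id": f"P{i}", "episode": ep,
                             "timepoint": tp, "time_days": day,
                             "binge_count": 3.0, "vomit_count": 1.0})
    return pd.DataFrame(rows)


class TestPreprocess:
    def test_first_episode_only_retained(self):
        df = _toy_long(episodes=(1, 2))
        out, log = preprocess(df)
        assert len(out) == 12
        assert {e["rule"] for e in log} == {"first_stay_only"}

    def test_count_outlier_flagged_not_dropped(self):
        df = _toy_long()
        df.loc[2, "binge_count"] = 501.0
        out, log = preprocess(df)
        assert len(out) == len(df)
        assert out.loc[out["participant_id"] == "P0", "exclude_from_counts"].all()
        assert any(e["rule"] == "count_outlier" for e in log)
        assert not out.loc[out["participant_id"] == "P1",
                           "exclude_from_counts"].any()

    def test_count_at_500_is_not_an_outlier(self):
        df = _toy_long()
        df.loc[2, "binge_count"] = 500.0
        out, _ = preprocess(df)
        assert not out["exclude_from_counts"].any()

    def test_clean_input_is_passthrough(self):
        df = _toy_long(n_participants=2)
        out, log = preprocess(df)
        assert log == []
        assert len(out) == len(df)

    def test_duplicate_rows_raise(self):
        df = pd.concat([_toy_long(), _toy_long().head(1)], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            preprocess(df)


class TestContrastCoding:
    def test_simple_coding_entries(self):
        values = pd.Series(["AN", "BN", "BED", "OSFED"])
        cols = simple_code(values, ["AN", "BN", "BED", "OSFED"], "AN")
        assert cols.shape == (4, 3)
        assert set(np.unique(cols.to_numpy())) == {0.75, -0.25}

    def test_two_level_simple_coding(self):
        cols = simple_code(pd.Series(["A", "B", "A"]), ["A", "B"], "A")
        assert list(cols.iloc[:, 0]) == [-0.5, 0.5, -0.5]

    def test_unknown_level_raises(self):
        with pytest.raises(ValidationError):
            simple_code(pd.Series(["A", "C"]), ["A", "B"], "A")

    def test_saturated_fit_recovers_level_mean_differences(self, rng):
        """With simple coding, coefficients equal level-vs-reference mean
        differences and the intercept is the grand mean of level means."""
        levels = ["AN", "BN", "BED"]
        values = pd.Series(rng.choice(levels, 300))
        true_means = {"AN": 2.0, "BN": 5.0, "BED": 3.5}
        y = values.map(true_means).to_numpy() + rng.normal(0, 1e-9, 300)
        X = np.column_stack([np.ones(300),
                             simple_code(values, levels, "AN").to_numpy()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        cell = {lev: y[values == lev].mean() for lev in levels}
        assert beta[0] == pytest.approx(np.mean(list(cell.values())), abs=1e-6)
        assert beta[1] == pytest.approx(cell["BN"] - cell["AN"], abs=1e-6)
        assert beta[2] == pytest.approx(cell["BED"] - cell["AN"], abs=1e-6)

    def test_region_dummies(self):
        values = pd.Series(["South", "West", "Midwest", "Northeast"])
        cols = region_dummies(values)
        assert list(cols.loc[0]) == [0.0, 0.0, 0.0]       # reference
        assert cols.loc[1, "region_West"] == 1.0
        # columns sum to 1 - I(South)
        assert list(cols.sum(axis=1)) == [0.0, 1.0, 1.0, 1.0]

    def test_unknown_region_raises(self):
        with pytest.raises(ValidationError):
            region_dummies(pd.Series(["Mars"]))


class TestBonferroni:
    def test_published_family_threshold(self):
        assert round(bonferroni(0.05, 17), 3) == 0.003

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (5, 0.01)])
    def test_simple_cases(self, m, expected):
        assert bonferroni(0.05, m) == pytest.approx(expected)


class TestLmmProfiledML:
    def test_matches_statsmodels_ml_on_unbalanced_data(self, rng):
        y, X, g = simulate_lmm(rng, 5, [1.0, 0.5, -0.3], 1.0, 0.5)
        fit = fit_lmm_ml(y, X, g)
        oracle = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert np.allclose(fit.params, oracle.fe_params, rtol=1e-4, atol=1e-6)
        assert fit.loglik == pytest.approx(oracle.llf, rel=1e-4)

    def test_lambda_zero_reduces_to_ols(self, rng):
        y, X, g = simulate_lmm(rng, 10, [2.0, 1.0], 1.0, 1.0)
        fit = fit_lmm_ml(y, X, g, lambda_fixed=0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(fit.params.to_numpy() - ols)) < 1e-8
        assert fit.sigma2_b == 0.0

    def test_profiled_deviance_unimodal_on_grid(self, rng):
        y, X, g = simulate_lmm(rng, 30, [1.0, 0.5], 2.0, 0.5)
        lams = np.exp(np.linspace(-6, 6, 120))
        dev = np.array([profiled_deviance(y, X, g, l) for l in lams])
        sign_changes = np.sum(np.diff(np.sign(np.diff(dev))) != 0)
        assert sign_changes <= 1  # single interior minimum

    def test_optimum_no_worse_than_nested_ols_start(self, rng):
        y, X, g = simulate_lmm(rng, 20, [1.0, -0.5], 1.5, 0.8)
        full = fit_lmm_ml(y, X, g)
        ols = fit_lmm_ml(y, X, g, lambda_fixed=0.0)
        assert full.loglik >= ols.loglik - 1e-10

    def test_boundary_sigma2b_zero_is_flagged(self, rng):
        # independent residuals: ML variance ratio collapses to zero
        y, X, g = simulate_lmm(rng, 40, [1.0, 0.3], 0.0, 1.0)
        fit = fit_lmm_ml(y, X, g)
        assert fit.sigma2_b < 0.05
        if fit.sigma2_b == 0.0:
            assert fit.boundary

    def test_single_participant_raises(self):
        with pytest.raises(ValidationError):
            fit_lmm_ml(np.ones(3), np.ones((3, 1)), np.zeros(3))

    def test_slope_recovery_single_large_replicate(self, rng):
        G, beta = 500, np.array([3.6, -0.02])
        t = np.tile([0.0, 30.0, 80.0], G)
        g = np.repeat(np.arange(G), 3)
        X = np.column_stack([np.ones(3 * G), t])
        b = rng.normal(0, 1.0, G)
        y = X @ beta + b[g] + rng.normal(0, 0.5, 3 * G)
        fit = fit_lmm_ml(y, X, g)
        assert fit.params.iloc[1] == pytest.approx(-0.02, abs=4 * fit.se.iloc[1])
        assert fit.sigma2_b == pytest.approx(1.0, abs=0.2)
        assert fit.sigma2_e == pytest.approx(0.25, abs=0.06)


class TestPartialR2:
    @pytest.fixture
    def fitted(self, rng):
        y, X, g = simulate_lmm(rng, 80, [1.0, 0.8, 0.0], 1.0, 1.0)
        return fit_lmm_ml(y, X, g, colnames=["intercept", "x1", "x2"],
                          terms={"intercept": [0], "x1": [1], "x2": [2]}), y, X, g

    def test_zero_wald_statistic_gives_zero_r2(self, fitted):
        fit, *_ = fitted
        fit.params.iloc[1] = 0.0  # force F = 0 for the term
        assert partial_r2(fit, "x1")["r2"] == 0.0

    def test_r2_bounded_and_larger_for_real_effect(self, fitted):
        fit, *_ = fitted
        r1 = partial_r2(fit, "x1")["r2"]
        r2 = partial_r2(fit, "x2")["r2"]
        assert 0.0 <= r2 < r1 <= 1.0

    def test_invariant_to_outcome_rescaling(self, fitted):
        fit, y, X, g = fitted
        names = list(fit.params.index)
        fit2 = fit_lmm_ml(10.0 * y, X, g, colnames=names, terms=fit.terms)
        assert partial_r2(fit2, "x1")["r2"] == pytest.approx(
            partial_r2(fit, "x1")["r2"], rel=1e-6)

    def test_bootstrap_ci_brackets_estimate(self, fitted, rng):
        fit, *_ = fitted
        res = partial_r2(fit, "x1", n_boot=50, rng=rng)
        lo, hi = res["ci"]
        assert 0.0 <= lo <= hi <= 1.0
        assert lo <= res["r2"] * 1.5  # CI overlaps the point estimate's scale

    def test_unknown_term_raises(self, fitted):
        with pytest.raises(ValidationError):
            partial_r2(fitted[0], "nope")


class TestNbGlmm:
    def _simulate(self, rng, G=150, beta=(1.2, -0.03), s2b=0.5, theta=1.5):
        t = np.tile([0.0, 30.0, 80.0], G)
        g = np.repeat(np.arange(G), 3)
        X = np.column_stack([np.ones(3 * G), t])
        b = rng.normal(0, np.sqrt(s2b), G)
        mu = np.exp(beta[0] + beta[1] * t + b[g])
        y = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)
        return y, X, g

    def test_poisson_glm_limit(self, rng):
        n = 300
        g = np.arange(n) // 3
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.8 + 0.4 * X[:, 1])).astype(float)
        fit = fit_nb_glmm(y, X, g, fix_sigma2_b=1e-8, fix_theta=1e7)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(fit.params.to_numpy() - glm.params)) < 1e-3

    def test_laplace_close_to_adaptive_quadrature_on_toys(self, rng):
        for _ in range(3):
            y, X, g = self._simulate(rng, G=10)
            fit = fit_nb_glmm(y, X, g)
            lap, _ = nb_laplace_loglik(fit.params.to_numpy(), fit.sigma2_b,
                                       fit.theta, y, X, g)
            agq = agq_loglik(fit.params.to_numpy(), fit.sigma2_b, fit.theta,
                             y, X, g, nodes=31)
            assert abs(lap - agq) / abs(agq) < 0.005

    def test_parameter_recovery_single_replicate(self, rng):
        y, X, g = self._simulate(rng, G=400, beta=(1.5, -0.05))
        fit = fit_nb_glmm(y, X, g)
        assert fit.params.iloc[1] == pytest.approx(-0.05, abs=4 * fit.se.iloc[1])
        assert 0.2 < fit.sigma2_b < 1.0
        assert 0.8 < fit.theta < 2.5

    def test_all_zero_counts_raise(self):
        with pytest.raises(DegenerateDataError):
            fit_nb_glmm(np.zeros(9), np.ones((9, 1)), np.arange(9) // 3)

    def test_non_integer_counts_raise(self):
        with pytest.raises(ValidationError):
            fit_nb_glmm(np.full(9, 1.5), np.ones((9, 1)), np.arange(9) // 3)


class TestDesignAndSpec:
    def test_interaction_main_effect_always_included(self, complete_cohort):
        data, _ = preprocess(complete_cohort.data)
        spec = ModelSpec(outcome="edeq_global", predictors=("time",),
                         interactions=("comorbid",))
        d = build_design(data, spec)
        assert "comorbid" in d.colnames
        assert "time_x_comorbid" in d.colnames

    def test_count_outliers_excluded_from_count_designs(self, complete_cohort):
        data, _ = preprocess(complete_cohort.data)
        spec = ModelSpec(outcome="binge_count", family="negbin")
        d = build_design(data, spec)
        flagged = set(data.loc[data["exclude_from_counts"], "participant_id"])
        assert flagged  # generator injects outliers by default
        assert d.y.max() <= 500

    def test_fit_lmm_from_spec_runs(self, complete_cohort):
        data, _ = preprocess(complete_cohort.data)
        fit = fit_lmm(data, ModelSpec(outcome="edeq_global"))
        assert fit.params["time"] < 0  # symptoms decline over treatment
        assert fit.sigma2_e > 0 and fit.sigma2_b >= 0


class TestMissingnessDiagnostics:
    def test_identical_groups_have_zero_smd(self):
        rows = []
        for i in range(40):
            for tp, day in [("admission", 0), ("stepdown", 30), ("discharge", 70)]:
                rows.append({"participant_id": i, "timepoint": tp,
                             "time_days": day, "age_admission": 15.0,
                             "admission_edeq": 3.0, "percent_ebw": 90.0,
                             "diagnosis": "AN-R", "comorbid": 1,
                             "gender": "cis_female", "loc_admit": "RES",
                             "discharge_reason": "routine",
                             "edeq_global": np.nan if (tp != "admission" and i % 2)
                             else 3.0, "phq9": np.nan, "gad7": np.nan})
        diag = missingness_diagnostics(pd.DataFrame(rows))
        smds = diag[diag["statistic"] == "smd"]["value"]
        assert np.allclose(smds, 0.0)

    def test_completion_rates_reported(self, default_cohort):
        data, _ = preprocess(default_cohort.data)
        diag = missingness_diagnostics(data)
        rates = diag[diag["statistic"] == "completion_rate"]
        assert set(rates["timepoint"]) == {"stepdown", "discharge"}
        assert ((rates["value"] > 0) & (rates["value"] < 1)).all()
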