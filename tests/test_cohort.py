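"""Synthetic cohort generator: mixtures, calibration, missingness, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from edhloc.cohort import (CohortConfig, MissingnessConfig, OutcomeTruth,
                           generate_cohort, generate_items, impose_missingness)
from edhloc.errors import ValidationError
from edhloc.mixed_models import ModelSpec, fit_lmm, preprocess
from edhloc.reliable_change import ChangeCategory, change_table, default_thresholds
from edhloc.scales import cronbach_alpha, default_scale_registry
from conftest import recovery_config


def _admissions(cohort):
    d = cohort.data
    return d[(d["timepoint"] == "admission") & (d["episode"] == 1)]


class TestGenerateCohort:
    def test_same_seed_gives_identical_output(self):
        cfg = CohortConfig(n_participants=150)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=5)
        assert a.data.equals(b.data)
        for key in a.items:
            assert a.items[key].equals(b.items[key])

    def test_different_seed_differs(self):
        cfg = CohortConfig(n_participants=150)
        assert not generate_cohort(cfg, seed=5).data.equals(
            generate_cohort(cfg, seed=6).data)

    def test_diagnosis_mixture_matches_targets(self, default_cohort):
        adm = _admissions(default_cohort)
        n = len(adm)
        props = adm["diagnosis"].value_counts(normalize=True)
        for level, p in default_cohort.config.diagnosis_mix.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(props.get(level, 0.0) - p) < 2.5 * se + 1e-9

    def test_admission_rows_at_day_zero(self, default_cohort):
        adm = _admissions(default_cohort)
        assert (adm["time_days"] == 0).all()
        d = default_cohort.data
        assert (d["time_days"] >= 0).all()

    def test_zero_variance_trajectories_sit_on_fixed_surface(self):
        cfg = dataclasses.replace(
            recovery_config(80),
            outcomes={"edeq_global": OutcomeTruth(3.0, -0.01, 0.0, 0.0),
                      "phq9": OutcomeTruth(14.0, -0.05, 0.0, 0.0),
                      "gad7": OutcomeTruth(12.0, -0.03, 0.0, 0.0)})
        c = generate_cohort(cfg, seed=11)
        d = c.data
        assert np.allclose(d["edeq_global"], 3.0 - 0.01 * d["time_days"])

    def test_an_admission_ebw_near_published_mean(self, default_cohort):
        adm = _admissions(default_cohort)
        an = adm[adm["diagnosis4"] == "AN"]["percent_ebw"].dropna()
        se = an.std() / np.sqrt(len(an))
        assert an.mean() == pytest.approx(87.46, abs=4 * se + 0.5)

    def test_truth_record_reconstructs_generating_parameters(self, default_cohort):
        truth = default_cohort.truth
        assert truth["outcomes"]["edeq_global"]["intercept"] == 3.62
        assert truth["config"]["n_participants"] == 2000
        assert "item_noise_variances" in truth

    def test_invalid_mixture_raises(self):
        cfg = dataclasses.replace(CohortConfig(), diagnosis_mix={"AN-R": 0.7})
        with pytest.raises(ValidationError):
            generate_cohort(cfg, seed=1)

    def test_seed_required(self):
        with pytest.raises(ValidationError):
            generate_cohort(CohortConfig(n_participants=10))

    def test_count_outliers_injected_for_preprocessing(self, complete_cohort):
        d = complete_cohort.data
        assert (d["binge_count"] > 500).any()
        assert len(complete_cohort.truth["count_outlier_ids"]) == 2


class TestGenerateItems:
    SPEC = default_scale_registry()["phq9"]

    def test_zero_noise_gives_alpha_near_one(self, rng):
        true = pd.Series(rng.normal(14.0, 7.0, 800))
        items, _ = generate_items(true, self.SPEC, 0.89, rng)
        # regenerate with the calibration bypassed: parallel items with no
        # continuous noise are perfectly correlated up to rounding
        item_true = (true / 9).to_numpy()[:, None]
        noiseless = np.clip(np.rint(np.repeat(item_true, 9, axis=1)), 0, 3)
        assert cronbach_alpha(noiseless) > 0.99

    def test_calibration_hits_target_alpha(self, rng):
        true = pd.Series(rng.normal(14.87, 7.08, 2000))
        items, noise_var = generate_items(true, self.SPEC, 0.89, rng)
        assert noise_var > 0
        assert cronbach_alpha(items.to_numpy()) == pytest.approx(0.89, abs=0.02)

    def test_missing_true_scores_propagate(self, rng):
        true = pd.Series([10.0, np.nan, 20.0, 12.0, 9.0])
        items, _ = generate_items(true, self.SPEC, 0.89, rng)
        assert items.iloc[1].isna().all()
        assert items.drop(index=1).notna().all().all()

    def test_infeasible_target_raises(self, rng):
        # near-zero true variance cannot support any alpha target
        true = pd.Series(np.full(100, 14.0) + rng.normal(0, 1e-4, 100))
        with pytest.raises(ValidationError):
            generate_items(true, self.SPEC, 0.9, rng)


class TestImposeMissingness:
    def test_marginal_rates_near_targets(self, default_cohort):
        d = default_cohort.data[default_cohort.data["episode"] == 1]
        sd = d[d["timepoint"] == "stepdown"]
        dc = d[d["timepoint"] == "discharge"]
        for frame, target in [(sd, 0.233), (dc, 0.556)]:
            frac = frame["edeq_global"].isna().mean()
            se = np.sqrt(target * (1 - target) / len(frame))
            assert abs(frac - target) < 2 * se + 1e-9

    def test_admission_never_missing(self, default_cohort):
        adm = _admissions(default_cohort)
        assert adm["edeq_global"].notna().all()

    def test_zero_target_leaves_cohort_complete(self, complete_cohort):
        cfg = MissingnessConfig(stepdown_rate=0.0, discharge_rate=0.0)
        out = impose_missingness(complete_cohort, config=cfg,
                                 rng=np.random.default_rng(3))
        assert out.data["edeq_global"].equals(complete_cohort.data["edeq_global"])

    def test_strong_covariate_effect_orders_conditional_rates(self):
        cfg = recovery_config(1500)
        c = generate_cohort(cfg, seed=21)
        strong = MissingnessConfig(
            stepdown_rate=0.3, discharge_rate=0.5,
            coefficients={"comorbid": 2.0})
        out = impose_missingness(c, config=strong, rng=np.random.default_rng(4))
        d = out.data[out.data["timepoint"] == "discharge"]
        miss = d["edeq_global"].isna()
        r1 = miss[d["comorbid"] == 1].mean()
        r0 = miss[d["comorbid"] == 0].mean()
        assert r1 > r0 + 0.1

    def test_item_matrices_nulled_consistently(self, default_cohort):
        d = default_cohort.data[default_cohort.data["episode"] == 1]
        dc = d[d["timepoint"] == "discharge"]
        miss_ids = set(dc.loc[dc["edeq_global"].isna(), "participant_id"])
        items = default_cohort.items[("edeq", "discharge")]
        assert items.loc[items.index.isin(miss_ids)].isna().all().all()


class TestEndToEndRecovery:
    def test_lmm_recovers_slope_under_mar(self):
        """Available-case ML on a MAR cohort recovers the generating slope —
        the property full-information ML relies on."""
        cfg = recovery_config(600)
        c = generate_cohort(cfg, seed=31)
        c = impose_missingness(c, rng=np.random.default_rng(32))
        data, _ = preprocess(c.data)
        fit = fit_lmm(data, ModelSpec(outcome="phq9"))
        assert fit.params["time"] == pytest.approx(-0.05, abs=4 * fit.se["time"])

    def test_change_table_modal_category_tracks_true_effect(self):
        thresholds = default_thresholds()["edeq"]
        base = recovery_config(800)
        big = dataclasses.replace(base, outcomes={
            "edeq_global": OutcomeTruth(4.2, -0.03, 1.2, 0.3),
            "phq9": OutcomeTruth(14.87, -0.05, 30.0, 20.0),
            "gad7": OutcomeTruth(12.93, -0.03, 20.0, 13.0)})
        null = dataclasses.replace(base, outcomes={
            "edeq_global": OutcomeTruth(4.2, 0.0, 1.2, 0.09),
            "phq9": OutcomeTruth(14.87, 0.0, 30.0, 20.0),
            "gad7": OutcomeTruth(12.93, 0.0, 20.0, 13.0)})

        def table(cfg, seed):
            c = generate_cohort(cfg, seed=seed)
            d = c.data
            wide = d.pivot_table(index="participant_id", columns="timepoint",
                                 values="edeq_global", aggfunc="first")
            pairs = wide[["admission", "discharge"]].rename(
                columns={"admission": "admit", "discharge": "followup"})
            return change_table(pairs, thresholds)

        strong = table(big, 41)
        modal = max(strong.counts, key=strong.counts.get)
        assert modal is ChangeCategory.clinically_significant

        none = table(null, 42)
        quiet = (none.counts[ChangeCategory.unchanged]
                 + none.counts[ChangeCategory.normative])
        assert quiet / none.n_reporting > 0.8
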