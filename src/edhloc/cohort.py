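"""Seeded synthetic cohort generator.

No participant-level data from the study this pipeline reproduces are
deposited, so every stage is exercised on synthetic cohorts that emulate the
study's structure: ~2,000 adolescents admitted to inpatient (IP),
residential (RES), partial hospitalization (PHP) or intensive outpatient
(IOP) eating-disorder programs, assessed at admission, stepdown and
discharge, with

* diagnosis / comorbidity / level-of-care / demographic mixtures matching
  the published sample composition,
* latent outcome trajectories from a random-intercept linear model whose
  admission means and SDs match the published descriptives and whose time
  slopes echo the published fixed-effect magnitudes,
* item-level responses calibrated (Spearman–Brown) so Cronbach's alpha hits
  the published reliabilities,
* negative-binomial binge/vomiting counts for binge-spectrum diagnoses,
* %EBW trajectories driving observed weights through the growth reference,
* covariate-dependent missing-at-random dropout at stepdown and discharge
  calibrated to the published marginal rates (23.3% / 55.6%).

Every generating parameter is recorded in a truth dictionary so parameter-
recovery tests can compare estimates against the exact simulation truth.
The measurement layer is switchable: ``include_items=True`` derives scores
from rounded, clipped items (realistic); ``False`` records the latent
Gaussian trajectories directly, the model-faithful mode used by recovery
simulations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError
from .growth import (GrowthReferenceTable, expected_body_weight,
                     synthetic_median_height, synthetic_reference)
from .scales import ScaleSpec, default_scale_registry, score_item_frame

__all__ = [
    "OutcomeTruth", "CountTruth", "EbwTruth", "MissingnessConfig",
    "CohortConfig", "SyntheticCohort",
    "generate_cohort", "generate_items", "impose_missingness",
]

TIMEPOINTS = ("admission", "stepdown", "discharge")

DIAGNOSIS_MIX = {"AN-R": 0.464, "AN-BP": 0.141, "BN": 0.057,
                 "BED": 0.019, "OSFED_UFED": 0.319}
LOC_MIX = {"IP": 0.153, "RES": 0.435, "PHP": 0.351, "IOP": 0.061}
GENDER_MIX = {"cis_female": 0.855, "cis_male": 0.071, "nonbinary": 0.049,
              "trans_ftm": 0.020, "trans_mtf": 0.005}  # normalized sample mix
DISCHARGE_MIX = {"routine": 0.667, "patient_request": 0.190, "required_other_care": 0.048,
                 "administrative": 0.043, "other": 0.017, "resource_constraint": 0.015,
                 "covid": 0.013, "ama": 0.009}
REGION_MIX = {"South": 0.35, "West": 0.25, "Midwest": 0.25, "Northeast": 0.15}
LOS_BY_LOC = {"IP": (25.93, 20.76), "RES": (42.72, 23.51),
              "PHP": (38.75, 20.00), "IOP": (45.49, 22.16)}


@dataclass(frozen=True)
class OutcomeTruth:
    """Generating parameters for one Gaussian outcome trajectory.

    ``slope_modifiers`` / ``intercept_modifiers`` map participant indicator
    columns to additive fixed-effect adjustments (the predictor-interaction
    truth for recovery tests).
    """

    intercept: float
    slope_per_day: float
    sigma2_b: float
    sigma2_e: float
    slope_modifiers: dict[str, float] = field(default_factory=dict)
    intercept_modifiers: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CountTruth:
    """NB2 truth for an episode-count outcome (log scale)."""

    intercept: float
    slope_per_day: float
    sigma2_b: float
    theta: float
    diagnoses: tuple[str, ...]


@dataclass(frozen=True)
class EbwTruth:
    """%EBW trajectory truth: person intercepts and per-day gain slopes."""

    intercept_mean: float
    intercept_sd: float
    slope_mean: float
    slope_sd: float
    sigma_e: float = 2.0


@dataclass(frozen=True)
class MissingnessConfig:
    """Logistic missing-at-random model for stepdown/discharge dropout.

    Coefficients act on participant-level covariates; the intercept is
    calibrated by bisection so the marginal missing fraction matches the
    target. Positive coefficients increase the odds of *missing* data.
    """

    stepdown_rate: float = 0.233
    discharge_rate: float = 0.556
    stepdown_eligible_rate: float = 1292 / 1971
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "cis_female": -0.3, "an_r": -0.3, "comorbid": -0.2,
        "routine_discharge": -0.4, "pebw_admission_z": 0.3,
    })


def _default_outcomes() -> dict[str, OutcomeTruth]:
    # Admission means/SDs match the published descriptives; slopes and
    # interaction magnitudes echo the published fixed-effect scale so that
    # sanity bands on fitted models are meaningful.
    return {
        "edeq_global": OutcomeTruth(
            intercept=3.62, slope_per_day=-0.015, sigma2_b=1.5, sigma2_e=1.0,
            slope_modifiers={"an_bp": -0.01, "comorbid": 0.01,
                             "dx_BN": -0.02, "dx_OSFED_UFED": -0.01},
        ),
        "phq9": OutcomeTruth(
            intercept=14.87, slope_per_day=-0.05, sigma2_b=30.0, sigma2_e=20.0,
            slope_modifiers={"dx_BN": -0.09, "dx_OSFED_UFED": -0.02,
                             "comorbid": 0.01},
            intercept_modifiers={"comorbid": 1.15},
        ),
        "gad7": OutcomeTruth(
            intercept=12.93, slope_per_day=-0.03, sigma2_b=20.0, sigma2_e=13.0,
            slope_modifiers={"dx_BN": -0.05},
        ),
    }


def _default_counts() -> dict[str, CountTruth]:
    return {
        "binge_count": CountTruth(intercept=1.4, slope_per_day=-0.04,
                                  sigma2_b=0.5, theta=1.5,
                                  diagnoses=("AN-BP", "BN", "BED")),
        "vomit_count": CountTruth(intercept=2.2, slope_per_day=-0.05,
                                  sigma2_b=0.8, theta=1.2,
                                  diagnoses=("AN-BP", "BN")),
    }


def _default_ebw() -> dict[str, EbwTruth]:
    # AN admission %EBW 87.46 (10.48) with a mean admission-to-discharge gain
    # of 16.43 (SD 10.87) over a ~80-day stay -> slope mean 16.43/80, person
    # slope SD 10.87/80. Non-AN values chosen so the full-sample mixture
    # reproduces the published full-sample descriptives.
    return {
        "AN": EbwTruth(intercept_mean=87.46, intercept_sd=10.48,
                       slope_mean=16.43 / 80.0, slope_sd=10.87 / 80.0),
        "other": EbwTruth(intercept_mean=117.0, intercept_sd=24.0,
                          slope_mean=0.09, slope_sd=0.08),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of the synthetic cohort.

    Defaults are the study conditions: sample size, mixtures, admission
    distributions, assessment timing and missingness targets as published.
    """

    n_participants: int = 1971
    diagnosis_mix: dict[str, float] = field(default_factory=lambda: dict(DIAGNOSIS_MIX))
    comorbidity_prevalence: float = 0.797
    loc_mix: dict[str, float] = field(default_factory=lambda: dict(LOC_MIX))
    gender_mix: dict[str, float] = field(default_factory=lambda: dict(GENDER_MIX))
    region_mix: dict[str, float] = field(default_factory=lambda: dict(REGION_MIX))
    discharge_mix: dict[str, float] = field(default_factory=lambda: dict(DISCHARGE_MIX))
    race_white_fraction: float = 0.806
    sex_female_fraction: float = 0.922
    age_mean: float = 14.84
    age_sd: float = 1.64
    age_min: float = 9.0
    age_max: float = 18.0
    los_mean: float = 79.97
    los_sd: float = 49.56
    los_max: float = 386.0
    los_by_loc: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LOS_BY_LOC))
    outcomes: dict[str, OutcomeTruth] = field(default_factory=_default_outcomes)
    counts: dict[str, CountTruth] = field(default_factory=_default_counts)
    ebw: dict[str, EbwTruth] = field(default_factory=_default_ebw)
    alpha_targets: dict[str, float] = field(default_factory=lambda: {
        "edeq": 0.96, "phq9": 0.89, "gad7": 0.90})
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    include_items: bool = True
    n_count_outliers: int = 2
    second_episode_fraction: float = 0.043

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValidationError("n_participants must be positive")
        for name, mix in [("diagnosis_mix", self.diagnosis_mix),
                          ("loc_mix", self.loc_mix),
                          ("region_mix", self.region_mix),
                          ("gender_mix", self.gender_mix),
                          ("discharge_mix", self.discharge_mix)]:
            total = sum(mix.values())
            # printed-table percentages carry rounding; draws renormalize
            if abs(total - 1.0) > 5e-3:
                raise ValidationError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in mix.values()):
                raise ValidationError(f"{name} has negative probabilities")
        for scale, truth in self.outcomes.items():
            if truth.sigma2_b < 0 or truth.sigma2_e < 0:
                raise ValidationError(f"{scale}: variance components must be >= 0")
        for rate in (self.missingness.stepdown_rate, self.missingness.discharge_rate):
            if not 0.0 <= rate < 1.0:
                raise ValidationError("missingness rates must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """Generated cohort: long data, item matrices, and the generating truth."""

    data: pd.DataFrame
    items: dict[tuple[str, str], pd.DataFrame]
    truth: dict
    config: CohortConfig

    def write(self, directory) -> None:
        """Write the cohort as CSV (long data, item matrices) + truth JSON."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(directory / "cohort.csv", index=False)
        for (scale, tp), frame in self.items.items():
            frame.to_csv(directory / f"items_{scale}_{tp}.csv")
        with open(directory / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=_json_default)


def _json_default(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Item generation
# ---------------------------------------------------------------------------

def spearman_brown_noise_variance(true_var: float, k: int, target_alpha: float,
                                  rounding_compensation: bool = True) -> float:
    """Parallel-item noise variance yielding a population alpha of ``target``.

    For k parallel items with per-item true-score variance ``true_var`` and
    error variance v, alpha = k*rho / (1 + (k-1)*rho) with
    rho = true_var / (true_var + v); inverting gives the required v.
    Rounding items to integers adds ~1/12 of error variance, which is
    subtracted from the continuous noise so discretized items still meet the
    target.
    """
    if not 0.0 < target_alpha < 1.0:
        raise ValidationError("target alpha must lie in (0, 1)")
    if true_var <= 0:
        raise ValidationError("true-score variance must be positive")
    rho = target_alpha / (k - target_alpha * (k - 1))
    v = true_var * (1.0 - rho) / rho
    if rounding_compensation:
        v -= 1.0 / 12.0
    if v <= 0:
        raise ValidationError(
            "target alpha infeasible after discretization; widen the item "
            "response range or lower the target")
    return v


def generate_items(true_scores, spec: ScaleSpec, target_alpha: float,
                   rng: np.random.Generator,
                   rounding_compensation: bool = True) -> tuple[pd.DataFrame, float]:
    """Item responses from true scores under a parallel-items model.

    Sum-scored scales split the true total evenly across items; mean-scored
    scales treat every item as parallel to the global score. Items are
    rounded to the response grid and clipped to the legal range. Returns the
    item frame and the continuous noise variance used.
    """
    true_scores = pd.Series(true_scores, dtype=float)
    k = spec.n_items
    item_true = true_scores / k if spec.scoring == "sum" else true_scores.copy()
    observed = item_true.dropna()
    if observed.size < 2:
        raise ValidationError("need >= 2 non-missing true scores")
    true_var = float(observed.var(ddof=0))
    noise_var = spearman_brown_noise_variance(true_var, k, target_alpha,
                                              rounding_compensation)
    noise = rng.normal(0.0, np.sqrt(noise_var), size=(len(true_scores), k))
    items = item_true.to_numpy()[:, None] + noise
    items = np.clip(np.rint(items), spec.item_min, spec.item_max)
    items[np.isnan(item_true.to_numpy()), :] = np.nan
    frame = pd.DataFrame(items, index=true_scores.index,
                         columns=[f"{spec.name}_item{j + 1:02d}" for j in range(k)])
    return frame, noise_var


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _choice(rng, mix: dict[str, float], size: int) -> np.ndarray:
    labels = list(mix)
    probs = np.asarray([mix[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=size, p=probs)


def _participants(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    pid = [f"P{i + 1:05d}" for i in range(n)]
    diagnosis = _choice(rng, config.diagnosis_mix, n)
    p = pd.DataFrame({"participant_id": pid, "diagnosis": diagnosis})
    p["diagnosis4"] = np.where(np.isin(diagnosis, ["AN-R", "AN-BP"]), "AN", diagnosis)
    p["an_bp"] = (diagnosis == "AN-BP").astype(int)
    p["an_r"] = (diagnosis == "AN-R").astype(int)
    for lev in ("BN", "BED", "OSFED_UFED"):
        p[f"dx_{lev}"] = (p["diagnosis4"] == lev).astype(int)
    p["comorbid"] = (rng.random(n) < config.comorbidity_prevalence).astype(int)
    p["loc_admit"] = _choice(rng, config.loc_mix, n)
    p["region"] = _choice(rng, config.region_mix, n)
    p["gender"] = _choice(rng, config.gender_mix, n)
    p["cis_female"] = (p["gender"] == "cis_female").astype(int)
    p["sex"] = np.where(rng.random(n) < config.sex_female_fraction, "female", "male")
    p["race"] = np.where(rng.random(n) < config.race_white_fraction,
                         "white", "nonwhite")
    p["age_admission"] = _truncnorm(rng, config.age_mean, config.age_sd,
                                    config.age_min, config.age_max, n)
    p["age_months"] = p["age_admission"] * 12.0
    height_med = synthetic_median_height("female", p["age_months"].to_numpy())
    height_med_m = synthetic_median_height("male", p["age_months"].to_numpy())
    med = np.where(p["sex"] == "female", height_med, height_med_m)
    p["height_m"] = med * np.exp(rng.normal(0.0, 0.035, n))
    p["los_total"] = _truncnorm(rng, config.los_mean, config.los_sd,
                                2.0, config.los_max, n)
    sd_mean = np.array([config.los_by_loc[l][0] for l in p["loc_admit"]])
    sd_sd = np.array([config.los_by_loc[l][1] for l in p["loc_admit"]])
    raw_step = rng.normal(sd_mean, sd_sd)
    p["stepdown_day"] = np.clip(raw_step, 1.0, p["los_total"] - 1.0)
    p["discharge_reason"] = _choice(rng, config.discharge_mix, n)
    p["routine_discharge"] = (p["discharge_reason"] == "routine").astype(int)
    p["stepdown_eligible"] = (
        rng.random(n) < config.missingness.stepdown_eligible_rate).astype(int)
    return p


def _latent_trajectories(p: pd.DataFrame, truth: OutcomeTruth,
                         times: np.ndarray, rng) -> np.ndarray:
    """n x 3 latent outcome values at the three assessment times."""
    n = len(p)
    slope = np.full(n, truth.slope_per_day)
    for cov, delta in truth.slope_modifiers.items():
        slope += delta * p[cov].to_numpy()
    intercept = np.full(n, truth.intercept)
    for cov, delta in truth.intercept_modifiers.items():
        intercept += delta * p[cov].to_numpy()
    b = rng.normal(0.0, np.sqrt(truth.sigma2_b), n)
    eps = rng.normal(0.0, np.sqrt(truth.sigma2_e), (n, times.shape[1]))
    return intercept[:, None] + slope[:, None] * times + b[:, None] + eps


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    reference: GrowthReferenceTable | None = None) -> SyntheticCohort:
    """Generate a complete (pre-missingness) synthetic cohort.

    Deterministic given (config, seed): the same inputs give byte-identical
    output. Apply :func:`impose_missingness` afterwards for the study's
    dropout structure.
    """
    config = config or CohortConfig()
    config.validate()
    if rng is None:
        if seed is None:
            raise ValidationError("a seed (or rng) is required")
        rng = np.random.default_rng(seed)
    reference = reference or synthetic_reference()
    registry = default_scale_registry()

    p = _participants(config, rng)
    n = len(p)
    times = np.column_stack([np.zeros(n), p["stepdown_day"], p["los_total"]])

    truth: dict = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "outcomes": {k: dataclasses.asdict(v) for k, v in config.outcomes.items()},
        "counts": {k: dataclasses.asdict(v) for k, v in config.counts.items()},
        "ebw": {k: dataclasses.asdict(v) for k, v in config.ebw.items()},
        "item_noise_variances": {},
    }

    latents = {name: _latent_trajectories(p, tr, times, rng)
               for name, tr in config.outcomes.items()}

    # counts: NB2 with log link for binge-spectrum diagnoses
    count_vals: dict[str, np.ndarray] = {}
    for name, tr in config.counts.items():
        vals = np.full((n, 3), np.nan)
        mask = p["diagnosis"].isin(tr.diagnoses).to_numpy()
        m = int(mask.sum())
        if m:
            b = rng.normal(0.0, np.sqrt(tr.sigma2_b), m)
            eta = tr.intercept + tr.slope_per_day * times[mask] + b[:, None]
            mu = np.exp(eta)
            # NB2 as gamma-mixed Poisson
            lam = rng.gamma(tr.theta, mu / tr.theta)
            vals[mask] = rng.poisson(lam).astype(float)
        count_vals[name] = vals

    # %EBW trajectories -> observed weights through the growth reference
    is_an = (p["diagnosis4"] == "AN").to_numpy()
    pebw = np.full((n, 3), np.nan)
    for grp, mask in [("AN", is_an), ("other", ~is_an)]:
        tr = config.ebw[grp]
        m = int(mask.sum())
        if not m:
            continue
        inter = rng.normal(tr.intercept_mean, tr.intercept_sd, m)
        slope = rng.normal(tr.slope_mean, tr.slope_sd, m)
        vals = inter[:, None] + slope[:, None] * times[mask] \
            + rng.normal(0.0, tr.sigma_e, (m, 3))
        pebw[mask] = np.clip(vals, 45.0, None)
    pebw[:, 1] = np.nan  # weights measured at intake and discharge only

    expected = np.array([
        expected_body_weight(sex, age_m, reference, height_m=h)
        for sex, age_m, h in zip(p["sex"], p["age_months"], p["height_m"])
    ])

    # scores: via items (realistic) or latent values directly (model-faithful)
    scores: dict[str, np.ndarray] = {}
    items: dict[tuple[str, str], pd.DataFrame] = {}
    scale_for = {"edeq_global": "edeq", "phq9": "phq9", "gad7": "gad7"}
    for outcome, latent in latents.items():
        scale = scale_for[outcome]
        spec = registry[scale]
        if config.include_items:
            scored = np.empty((n, 3))
            for t, tp in enumerate(TIMEPOINTS):
                frame, noise_var = generate_items(
                    pd.Series(latent[:, t], index=p["participant_id"]),
                    spec, config.alpha_targets[scale], rng)
                items[(scale, tp)] = frame
                truth["item_noise_variances"][f"{scale}_{tp}"] = noise_var
                scored[:, t] = score_item_frame(frame, spec).to_numpy()
            scores[outcome] = scored
        else:
            scores[outcome] = latent

    # assemble the long frame
    rows = []
    participant_cols = [c for c in p.columns if c not in ("stepdown_day",)]
    for t, tp in enumerate(TIMEPOINTS):
        block = p[participant_cols].copy()
        block["episode"] = 1
        block["timepoint"] = tp
        block["time_days"] = times[:, t]
        for outcome in scores:
            block[outcome] = scores[outcome][:, t]
        for name in count_vals:
            block[name] = count_vals[name][:, t]
        block["percent_ebw"] = pebw[:, t]
        block["expected_weight_kg"] = expected
        block["weight_kg"] = pebw[:, t] / 100.0 * expected
        if tp == "stepdown":
            block = block[block["stepdown_eligible"] == 1]
        rows.append(block)
    data = pd.concat(rows, ignore_index=True)
    admission_edeq = data.loc[data["timepoint"] == "admission",
                              ["participant_id", "edeq_global"]]
    data = data.merge(admission_edeq.rename(columns={"edeq_global": "admission_edeq"}),
                      on="participant_id", how="left")

    # inject implausible self-reported episode counts (removed by preprocessing)
    eligible = data.loc[data["binge_count"].notna(), "participant_id"].unique()
    n_out = min(config.n_count_outliers, len(eligible))
    if n_out:
        chosen = rng.choice(eligible, size=n_out, replace=False)
        mask = (data["participant_id"].isin(chosen)) & (data["timepoint"] == "admission")
        data.loc[mask, "binge_count"] = rng.integers(501, 900, size=int(mask.sum())).astype(float)
        truth["count_outlier_ids"] = list(chosen)

    # later treatment episodes (dropped by first-stay preprocessing); scores
    # are latent redraws — these rows never reach analysis
    n_second = int(round(config.second_episode_fraction * n))
    if n_second:
        chosen = rng.choice(p["participant_id"], size=n_second, replace=False)
        sub = data[(data["participant_id"].isin(chosen))].copy()
        sub["episode"] = 2
        for outcome in scores:
            sub[outcome] = sub[outcome] + rng.normal(0.0, 0.5, len(sub))
        data = pd.concat([data, sub], ignore_index=True)
        truth["second_episode_ids"] = list(chosen)

    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    data = data.sort_values(
        ["participant_id", "episode", "timepoint"],
        key=lambda s: s.map(order) if s.name == "timepoint" else s,
    ).reset_index(drop=True)
    return SyntheticCohort(data=data, items=items, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("edeq_global", "phq9", "gad7", "binge_count", "vomit_count")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Bisection on the logit intercept so mean(sigmoid(a + lin)) = target."""
    f = lambda a: _sigmoid(a + lin).mean() - target
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:  # pragma: no cover
        raise ValidationError("missingness target unattainable given covariate effects")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def impose_missingness(cohort: SyntheticCohort,
                       config: MissingnessConfig | None = None,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> SyntheticCohort:
    """Null self-report scores at stepdown/discharge under a logistic MAR model.

    Admission assessments are never missing, and weights (staff-measured)
    are retained. Calibrated intercepts are recorded in the truth dict.
    """
    config = config or cohort.config.missingness
    if rng is None:
        if seed is None:
            raise ValidationError("a seed (or rng) is required")
        rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    adm = data[(data["timepoint"] == "admission") & (data["episode"] == 1)]
    adm = adm.drop_duplicates("participant_id").set_index("participant_id")
    cov = pd.DataFrame(index=adm.index)
    pebw = adm["percent_ebw"]
    cov["pebw_admission_z"] = ((pebw - pebw.mean()) / pebw.std(ddof=0)).fillna(0.0)
    for col in ("cis_female", "an_r", "comorbid", "routine_discharge"):
        cov[col] = adm[col]
    lin_full = np.zeros(len(cov))
    for name, coef in config.coefficients.items():
        lin_full += coef * cov[name].to_numpy(dtype=float)
    lin = pd.Series(lin_full, index=cov.index)

    truth = dict(cohort.truth)
    truth.setdefault("missingness", {})
    items = {k: v.copy() for k, v in cohort.items.items()}
    for tp, target in [("stepdown", config.stepdown_rate),
                       ("discharge", config.discharge_rate)]:
        rows = data[(data["timepoint"] == tp) & (data["episode"] == 1)]
        pids = rows["participant_id"].to_numpy()
        lin_tp = lin.reindex(pids).to_numpy()
        if target <= 0:
            continue
        a = _calibrate_intercept(lin_tp, target)
        miss = rng.random(len(pids)) < _sigmoid(a + lin_tp)
        miss_ids = set(pids[miss])
        sel = data.index.isin(rows.index) & data["participant_id"].isin(miss_ids)
        data.loc[sel, list(SCORE_COLUMNS)] = np.nan
        for (scale, item_tp), frame in items.items():
            if item_tp == tp:
                frame.loc[frame.index.isin(miss_ids), :] = np.nan
        truth["missingness"][tp] = {"intercept": a, "target": target,
                                    "n_missing": int(miss.sum()),
                                    "n_eligible": int(len(pids))}
    data["missing_stepdown"] = ~data["participant_id"].isin(
        data.loc[(data["timepoint"] == "stepdown") & data["edeq_global"].notna(),
                 "participant_id"])
    return SyntheticCohort(data=data, items=items, truth=truth, config=cohort.config)
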