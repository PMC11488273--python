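"""End-to-end orchestration: simulate/load -> score -> classify -> model -> report.

``run_pipeline`` executes the full outcome analysis on either a synthetic
cohort or a long-format CSV and writes a ReportBundle of plain CSV/markdown
tables: descriptives, reliable/clinically-significant change tables per
admitting group, mixed-model tables (aim-1 per subsample, pooled predictor
models, post-hoc region models), count-model tables, missingness
diagnostics, and a manifest recording seed, configuration hash and package
versions so every reported number is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (CohortConfig, SyntheticCohort, generate_cohort,
                     impose_missingness)
from .errors import ConvergenceError, ValidationError
from .growth import GrowthReferenceTable, expected_body_weight, percent_ebw, \
    synthetic_reference
from .mixed_models import (ModelSpec, bonferroni, fit_lmm, fit_nb,
                           missingness_diagnostics, partial_r2, preprocess)
from .reliable_change import (CATEGORY_ORDER, ChangeTable, change_table,
                              default_thresholds)
from .scales import cronbach_alpha, default_scale_registry

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_change_table",
           "aim1_model_specs", "predictor_model_specs"]

SUBSAMPLES = {"ip_res": ("IP", "RES"), "php_iop": ("PHP", "IOP")}
SCALE_OUTCOMES = {"edeq": "edeq_global", "phq9": "phq9", "gad7": "gad7"}

#: Number of models across both aims used for the family-wise Bonferroni
#: threshold (0.05 / 17).
N_TESTS_FAMILY = 17


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration.

    Either ``input_csv`` (long-format cohort CSV) or a synthetic
    ``cohort_config`` drives the run; a seed is mandatory because the
    synthetic generator, missingness and bootstrap are stochastic.
    """

    seed: int
    output_dir: str = "results/pipeline"
    input_csv: str | None = None
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    apply_missingness: bool = True
    growth_reference_csv: str | None = None
    bootstrap_reps: int = 200
    alpha_family: float = 0.05
    n_tests: int = N_TESTS_FAMILY

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    descriptives: pd.DataFrame
    thresholds: pd.DataFrame
    change_tables: dict[str, pd.DataFrame]
    model_tables: dict[str, pd.DataFrame]
    missingness: pd.DataFrame
    reliability: pd.DataFrame
    manifest: dict
    exclusions: list[dict]


def aim1_model_specs() -> list[ModelSpec]:
    """Symptom-change models: outcome ~ time + age + LOS, per subsample."""
    specs = []
    for scale, outcome in SCALE_OUTCOMES.items():
        for sub in SUBSAMPLES:
            specs.append(ModelSpec(outcome=outcome, name=f"aim1_{scale}_{sub}"))
    for sub in SUBSAMPLES:
        specs.append(ModelSpec(outcome="percent_ebw", name=f"aim1_ebw_{sub}"))
        specs.append(ModelSpec(outcome="binge_count", family="negbin",
                               name=f"aim1_binge_{sub}"))
        specs.append(ModelSpec(outcome="vomit_count", family="negbin",
                               name=f"aim1_vomit_{sub}"))
    return specs


def predictor_model_specs(post_hoc_region: bool = False) -> list[ModelSpec]:
    """Pooled predictor models with predictor x time interactions."""
    interactions = ("age", "an_bp", "comorbid", "diagnosis", "admission_edeq")
    extra = ("region", "loc") if post_hoc_region else ()
    tag = "region_" if post_hoc_region else ""
    specs = [
        ModelSpec(outcome=out, predictors=("time", "age", "los") + extra,
                  interactions=interactions, name=f"pred_{tag}{scale}")
        for scale, out in SCALE_OUTCOMES.items()
    ]
    specs.append(ModelSpec(outcome="percent_ebw",
                           predictors=("time", "age", "los") + extra,
                           interactions=("age", "an_bp", "comorbid",
                                         "admission_edeq"),
                           name=f"pred_{tag}ebw"))
    specs.append(ModelSpec(outcome="binge_count", family="negbin",
                           predictors=("time", "age", "los") + extra,
                           interactions=("age", "comorbid", "diagnosis_counts",
                                         "admission_edeq"),
                           name=f"pred_{tag}binge"))
    specs.append(ModelSpec(outcome="vomit_count", family="negbin",
                           predictors=("time", "age", "los") + extra,
                           interactions=("age", "comorbid", "admission_edeq"),
                           name=f"pred_{tag}vomit"))
    return specs


def _descriptives(data: pd.DataFrame) -> pd.DataFrame:
    rows = []

    def add(label, series):
        s = pd.to_numeric(series, errors="coerce").dropna()
        if s.empty:
            return
        rows.append({"variable": label, "mean": s.mean(), "sd": s.std(ddof=1),
                     "min": s.min(), "max": s.max(), "n": len(s)})

    adm = data[data["timepoint"] == "admission"]
    add("age_admission", adm["age_admission"])
    add("los_total", adm["los_total"])
    an = data["diagnosis4"] == "AN"
    for tp in ("admission", "stepdown", "discharge"):
        sub = data[data["timepoint"] == tp]
        for scale, outcome in SCALE_OUTCOMES.items():
            add(f"{scale}_{tp}", sub[outcome])
        if tp != "stepdown":
            add(f"percent_ebw_full_{tp}", sub["percent_ebw"])
            add(f"percent_ebw_an_{tp}", sub.loc[an.reindex(sub.index, fill_value=False),
                                                "percent_ebw"])
    return pd.DataFrame(rows)


def render_change_table(tables: dict[tuple[str, str], ChangeTable],
                        group_label: str) -> tuple[pd.DataFrame, str]:
    """CSV frame + footnoted markdown for one admitting group's change tables."""
    rows = []
    for (scale, interval), tab in sorted(tables.items()):
        pct = tab.percentages
        row = {"scale": scale, "interval": interval,
               **{c.value: round(pct[c], 1) for c in CATEGORY_ORDER},
               "n_reporting": tab.n_reporting,
               "sum_check": round(sum(pct.values()), 1)}
        rows.append(row)
    frame = pd.DataFrame(rows)
    lines = [f"## Reliable and clinically significant change — {group_label}", ""]
    header = ("| Scale | Interval | CSC %a | Reliable %b | Unchanged %c | "
              "Deteriorated %d | Normative %e | n |")
    lines += [header, "|" + "---|" * 8]
    for r in rows:
        lines.append(
            f"| {r['scale']} | {r['interval']} | {r['clinically_significant']} | "
            f"{r['improved']} | {r['unchanged']} | {r['deteriorated']} | "
            f"{r['normative']} | {r['n_reporting']} |")
    lines += [
        "",
        "a Among those in the clinical range at admission: met the reliable-change "
        "criterion and crossed the clinical cutoff into the normative range.",
        "b Among those in the clinical range: met the reliable-change criterion but "
        "did not cross the cutoff.",
        "c Among those in the clinical range: did not meet the reliable-change "
        "criterion.",
        "d Met the reliable-change criterion in the opposite direction (worsened).",
        "e Scores within the normal range of functioning at both timepoints.",
        "",
        "Percentages are of the reporting sample (both assessments present) and "
        "sum to 100 up to rounding.",
    ]
    return frame, "\n".join(lines)


def _model_table(fit, spec: ModelSpec, threshold: float,
                 bootstrap_reps: int, rng) -> pd.DataFrame:
    frame = fit.summary_frame()
    frame.insert(0, "term", frame.index)
    frame["significant"] = frame["p"] < threshold
    if spec.family == "gaussian" and fit.terms:
        r2s, lo, hi = [], [], []
        for name in frame.index:
            term = _owning_term(fit.terms, name, frame.index)
            try:
                res = partial_r2(fit, term, n_boot=bootstrap_reps, rng=rng)
            except ValidationError:
                res = {"r2": np.nan, "ci": (np.nan, np.nan)}
            r2s.append(res.get("r2", np.nan))
            ci = res.get("ci", (np.nan, np.nan))
            lo.append(ci[0]); hi.append(ci[1])
        frame["partial_r2"] = r2s
        frame["r2_ci_lo"] = lo
        frame["r2_ci_hi"] = hi
    frame["model"] = spec.label
    return frame.reset_index(drop=True)


def _owning_term(terms: dict[str, list[int]], colname: str,
                 colnames: pd.Index) -> str:
    pos = list(colnames).index(colname)
    for term, cols in terms.items():
        if pos in cols:
            return term
    raise ValidationError(f"no term owns column {colname!r}")


def _load_cohort(config: RunConfig) -> SyntheticCohort:
    if config.input_csv is not None:
        data = pd.read_csv(config.input_csv)
        return SyntheticCohort(data=data, items={}, truth={}, config=config.cohort_config)
    cohort = generate_cohort(config.cohort_config, seed=config.seed)
    if config.apply_missingness:
        cohort = impose_missingness(
            cohort, rng=np.random.default_rng(config.seed + 1))
    return cohort


def run_pipeline(config: RunConfig, write: bool = True) -> ReportBundle:
    """Run the full analysis; optionally write the bundle under output_dir."""
    if config.seed is None:
        raise ValidationError("a seed is required")
    rng = np.random.default_rng(config.seed + 2)
    cohort = _load_cohort(config)
    data, exclusions = preprocess(cohort.data)

    reference = (GrowthReferenceTable.from_csv(config.growth_reference_csv)
                 if config.growth_reference_csv else synthetic_reference())
    # recompute %EBW from observed weight/height/age through the reference;
    # participants outside the reference age grid are excluded from weight rows
    if {"weight_kg", "height_m", "age_months"}.issubset(data.columns):
        pebw = np.full(len(data), np.nan)
        for i, (w, h, a, sex) in enumerate(zip(data["weight_kg"], data["height_m"],
                                               data["age_months"], data["sex"])):
            if np.isnan(w) or np.isnan(h):
                continue
            try:
                exp_w = expected_body_weight(sex, a, reference, height_m=h)
                pebw[i] = percent_ebw(w, exp_w)
            except ValidationError:
                exclusions.append({"participant_id": data["participant_id"].iloc[i],
                                   "rule": "age_outside_reference",
                                   "detail": f"age {a} months outside grid"})
        data["percent_ebw"] = pebw

    registry = default_scale_registry()
    thresholds = default_thresholds(registry)
    thr_frame = pd.DataFrame([
        {"scale": name, "rci_threshold": round(t.rci_threshold, 2),
         "cs_cutoff": t.cs_cutoff, "z": t.confidence_z}
        for name, t in thresholds.items()
    ])

    # internal consistency per scale x timepoint from item matrices
    rel_rows = []
    for (scale, tp), frame in cohort.items.items():
        try:
            rel_rows.append({"scale": scale, "timepoint": tp,
                             "cronbach_alpha": cronbach_alpha(frame.to_numpy())})
        except ValidationError:
            pass
    reliability = pd.DataFrame(rel_rows)

    # change tables per admitting group and interval
    change_frames: dict[str, pd.DataFrame] = {}
    change_md: dict[str, str] = {}
    adm = data[data["timepoint"] == "admission"].set_index("participant_id")
    for sub, locs in SUBSAMPLES.items():
        pids = adm.index[adm["loc_admit"].isin(locs)]
        tables = {}
        for scale, outcome in SCALE_OUTCOMES.items():
            wide = (data[data["participant_id"].isin(pids)]
                    .pivot_table(index="participant_id", columns="timepoint",
                                 values=outcome, aggfunc="first"))
            for interval, col in [("admit_to_stepdown", "stepdown"),
                                  ("admit_to_discharge", "discharge")]:
                if "admission" not in wide.columns or col not in wide.columns:
                    continue
                pairs = wide[["admission", col]].rename(
                    columns={"admission": "admit", col: "followup"})
                try:
                    tables[(scale, interval)] = change_table(
                        pairs, thresholds[scale], interval)
                except ValidationError:
                    continue
        frame, md = render_change_table(tables, sub)
        change_frames[sub] = frame
        change_md[sub] = md

    # models
    threshold = bonferroni(config.alpha_family, config.n_tests)
    model_tables: dict[str, pd.DataFrame] = {}
    an_data = data[data["diagnosis4"] == "AN"]
    for spec in aim1_model_specs():
        locs = SUBSAMPLES[spec.name.split("_", 2)[2]]
        base = an_data if spec.outcome == "percent_ebw" else data
        subset = base[base["loc_admit"].isin(locs)]
        model_tables[spec.label] = _fit_one(subset, spec, threshold,
                                            config.bootstrap_reps, rng)
    for spec in predictor_model_specs():
        base = an_data if spec.outcome == "percent_ebw" else data
        model_tables[spec.label] = _fit_one(base, spec, threshold,
                                            config.bootstrap_reps, rng)
    for spec in predictor_model_specs(post_hoc_region=True):
        base = an_data if spec.outcome == "percent_ebw" else data
        model_tables[spec.label] = _fit_one(base, spec, threshold,
                                            config.bootstrap_reps, rng)

    missing = missingness_diagnostics(data)
    descriptives = _descriptives(data)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_participants": int(data["participant_id"].nunique()),
        "n_rows": int(len(data)),
        "bonferroni_threshold": threshold,
        "models": sorted(model_tables),
        "exclusions": len(exclusions),
    }
    bundle = ReportBundle(descriptives=descriptives, thresholds=thr_frame,
                          change_tables=change_frames, model_tables=model_tables,
                          missingness=missing, reliability=reliability,
                          manifest=manifest, exclusions=exclusions)
    if write:
        _write_bundle(bundle, change_md, config)
    return bundle


def _fit_one(subset: pd.DataFrame, spec: ModelSpec, threshold: float,
             bootstrap_reps: int, rng) -> pd.DataFrame:
    try:
        if spec.family == "gaussian":
            fit = fit_lmm(subset, spec)
        else:
            fit = fit_nb(subset, spec)
    except (ValidationError, ConvergenceError) as exc:
        # small subsamples can leave a count model unidentified; report the
        # failure in the table rather than aborting the whole bundle
        return pd.DataFrame([{"model": spec.label, "error": str(exc)}])
    return _model_table(fit, spec, threshold, bootstrap_reps, rng)


def _write_bundle(bundle: ReportBundle, change_md: dict[str, str],
                  config: RunConfig) -> None:
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.descriptives.to_csv(out / "descriptives.csv", index=False)
    bundle.thresholds.to_csv(out / "thresholds.csv", index=False)
    bundle.reliability.to_csv(out / "reliability.csv", index=False)
    bundle.missingness.to_csv(out / "missingness.csv", index=False)
    for sub, frame in bundle.change_tables.items():
        frame.to_csv(out / f"change_table_{sub}.csv", index=False)
        (out / f"change_table_{sub}.md").write_text(change_md[sub])
    models = pd.concat([f for f in bundle.model_tables.values()],
                       ignore_index=True)
    models.to_csv(out / "model_tables.csv", index=False)
    pd.DataFrame(bundle.exclusions).to_csv(out / "exclusions.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
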