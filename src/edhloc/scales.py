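"""Scoring of the three self-report instruments and internal consistency.

The pipeline scores three adolescent self-report measures:

* EDE-Q — Eating Disorder Examination–Questionnaire. We use the global
  score: the mean of four attitudinal subscale scores (restraint, eating
  concern, shape concern, weight concern), each subscale the mean of its
  items on a 0–6 scale. The subscale membership map is configuration data
  (``ScaleSpec.subscales``), not code, so alternative scoring maps can be
  supplied without touching the scorer.
* PHQ-9 — nine depression items rated 0–3, summed (range 0–27).
* GAD-7 — seven anxiety items rated 0–3, summed (range 0–21).

Internal consistency is estimated with Cronbach's alpha on listwise-complete
item matrices, using the population (1/n) variance convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "ScaleSpec",
    "EDEQ_SUBSCALES",
    "default_scale_registry",
    "load_scale_registry",
    "score_sum_scale",
    "score_phq9",
    "score_gad7",
    "score_edeq_global",
    "score_item_frame",
    "cronbach_alpha",
]

#: Default partition of the 22 attitudinal EDE-Q items into four subscales.
#: The published instrument shares one item between the shape- and
#: weight-concern subscales; a partition is required here, so the shared item
#: is assigned to weight concern. Supply a different map via ScaleSpec to
#: change this.
EDEQ_SUBSCALES: dict[int, str] = {
    **{i: "restraint" for i in range(5)},
    **{i: "eating_concern" for i in range(5, 10)},
    **{i: "shape_concern" for i in range(10, 17)},
    **{i: "weight_concern" for i in range(17, 22)},
}


@dataclass(frozen=True)
class ScaleSpec:
    """Metadata for one instrument.

    Parameters
    ----------
    name : str
        Scale identifier, e.g. ``"edeq"``.
    n_items : int
        Number of scored items.
    item_min, item_max : float
        Bounds of the item response scale.
    scoring : {"sum", "subscale_mean"}
        ``sum`` adds item responses; ``subscale_mean`` averages subscale
        means (EDE-Q global).
    subscales : dict[int, str] or None
        Item index -> subscale label; required for ``subscale_mean``.
    reliability_alpha : float
        Internal consistency at admission; drives the reliable-change
        threshold.
    admission_sd : float
        Admission standard deviation of the scored scale.
    clinical_cutoff : float
        Clinical-significance cutoff (criterion "c") separating the clinical
        from the normative range.
    direction : str
        Only ``"higher_is_worse"`` is supported: larger scores mean more
        severe symptoms.
    """

    name: str
    n_items: int
    item_min: float
    item_max: float
    scoring: str
    reliability_alpha: float
    admission_sd: float
    clinical_cutoff: float
    subscales: dict[int, str] | None = None
    direction: str = "higher_is_worse"
    admission_mean: float | None = None

    def __post_init__(self) -> None:
        if self.n_items <= 1:
            raise ValidationError(f"{self.name}: n_items must exceed 1")
        if not self.item_min < self.item_max:
            raise ValidationError(f"{self.name}: item_min must be < item_max")
        if not 0.0 <= self.reliability_alpha <= 1.0:
            raise ValidationError(f"{self.name}: reliability_alpha outside [0, 1]")
        if self.admission_sd <= 0:
            raise ValidationError(f"{self.name}: admission_sd must be positive")
        if self.scoring not in ("sum", "subscale_mean"):
            raise ValidationError(f"{self.name}: unknown scoring rule {self.scoring!r}")
        if self.scoring == "subscale_mean":
            if not self.subscales:
                raise ValidationError(f"{self.name}: subscale_mean scoring needs a subscale map")
            if set(self.subscales) != set(range(self.n_items)):
                raise ValidationError(f"{self.name}: subscale map must cover items 0..{self.n_items - 1}")
        if self.direction != "higher_is_worse":
            raise ValidationError(f"{self.name}: unsupported direction {self.direction!r}")
        lo, hi = self.score_range
        if not lo <= self.clinical_cutoff <= hi:
            raise ValidationError(f"{self.name}: clinical_cutoff outside score range")

    @property
    def score_range(self) -> tuple[float, float]:
        if self.scoring == "sum":
            return self.n_items * self.item_min, self.n_items * self.item_max
        return float(self.item_min), float(self.item_max)

    @property
    def subscale_items(self) -> dict[str, list[int]]:
        if self.subscales is None:
            return {}
        out: dict[str, list[int]] = {}
        for idx, label in self.subscales.items():
            out.setdefault(label, []).append(idx)
        return {k: sorted(v) for k, v in out.items()}


def default_scale_registry() -> dict[str, ScaleSpec]:
    """Registry with study defaults.

    Reliabilities are the admission-timepoint values of each printed range;
    admission SDs and clinical cutoffs are the published study constants.
    """
    return {
        "edeq": ScaleSpec(
            name="edeq", n_items=22, item_min=0, item_max=6,
            scoring="subscale_mean", subscales=dict(EDEQ_SUBSCALES),
            reliability_alpha=0.96, admission_sd=1.59, clinical_cutoff=2.71,
            admission_mean=3.62,
        ),
        "phq9": ScaleSpec(
            name="phq9", n_items=9, item_min=0, item_max=3, scoring="sum",
            reliability_alpha=0.89, admission_sd=7.08, clinical_cutoff=9.48,
            admission_mean=14.87,
        ),
        "gad7": ScaleSpec(
            name="gad7", n_items=7, item_min=0, item_max=3, scoring="sum",
            reliability_alpha=0.90, admission_sd=5.74, clinical_cutoff=7.97,
            admission_mean=12.93,
        ),
    }


def load_scale_registry(path) -> dict[str, ScaleSpec]:
    """Load a ScaleSpec registry from a YAML file.

    The file maps scale name -> ScaleSpec fields; ``subscales`` keys are
    item indices (ints).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for name, fields in raw.items():
        subscales = fields.pop("subscales", None)
        if subscales is not None:
            subscales = {int(k): v for k, v in subscales.items()}
        registry[name] = ScaleSpec(name=name, subscales=subscales, **fields)
    return registry


def _check_items(items: np.ndarray, spec: ScaleSpec) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    if items.shape[-1] != spec.n_items:
        raise ValidationError(
            f"{spec.name}: expected {spec.n_items} items, got {items.shape[-1]}"
        )
    present = ~np.isnan(items)
    if np.any((items[present] < spec.item_min) | (items[present] > spec.item_max)):
        raise ValidationError(f"{spec.name}: item responses outside "
                              f"[{spec.item_min}, {spec.item_max}]")
    return items


def score_sum_scale(items, spec: ScaleSpec, proration_max_missing: int = 0) -> float:
    """Sum score with optional proration of missing items.

    With proration enabled (``proration_max_missing`` > 0) and at most that
    many items missing, the score is the mean of present items scaled to the
    full item count and rounded to the nearest integer. More missing items
    than allowed yields ``nan``.
    """
    items = _check_items(np.asarray(items, dtype=float).ravel(), spec)
    n_missing = int(np.isnan(items).sum())
    if n_missing == 0:
        return float(items.sum())
    if n_missing > proration_max_missing:
        return float("nan")
    prorated = np.nanmean(items) * spec.n_items
    return float(np.rint(prorated))


def score_phq9(items, proration_max_missing: int = 0,
               spec: ScaleSpec | None = None) -> float:
    """PHQ-9 total score (0–27)."""
    spec = spec or default_scale_registry()["phq9"]
    return score_sum_scale(items, spec, proration_max_missing)


def score_gad7(items, proration_max_missing: int = 0,
               spec: ScaleSpec | None = None) -> float:
    """GAD-7 total score (0–21)."""
    spec = spec or default_scale_registry()["gad7"]
    return score_sum_scale(items, spec, proration_max_missing)


def score_edeq_global(items, spec: ScaleSpec | None = None,
                      min_present_frac: float = 0.5) -> float:
    """EDE-Q global score: mean of the four attitudinal subscale means.

    Each subscale score is the mean of its present items provided at least
    ``min_present_frac`` of the subscale's items are present (>= 1/2 by
    default, the common convention); otherwise the global score is missing.
    """
    spec = spec or default_scale_registry()["edeq"]
    items = _check_items(np.asarray(items, dtype=float).ravel(), spec)
    subscale_means = []
    for _, idxs in sorted(spec.subscale_items.items()):
        vals = items[idxs]
        n_present = int((~np.isnan(vals)).sum())
        if n_present < min_present_frac * len(idxs):
            return float("nan")
        subscale_means.append(float(np.nanmean(vals)))
    return float(np.mean(subscale_means))


def score_item_frame(frame: pd.DataFrame, spec: ScaleSpec,
                     proration_max_missing: int = 0,
                     min_present_frac: float = 0.5) -> pd.Series:
    """Score every row of a wide item matrix (one row per respondent)."""
    arr = frame.to_numpy(dtype=float)
    if spec.scoring == "sum":
        scores = [score_sum_scale(row, spec, proration_max_missing) for row in arr]
    else:
        scores = [score_edeq_global(row, spec, min_present_frac) for row in arr]
    return pd.Series(scores, index=frame.index, name=spec.name)


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha with listwise deletion.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total), population (1/n)
    variances. Requires >= 2 items and >= 3 complete rows; degenerate data
    (zero total variance) raises.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("cronbach_alpha needs a 2-D matrix with >= 2 items")
    complete = arr[~np.isnan(arr).any(axis=1)]
    if complete.shape[0] < 3:
        raise ValidationError(
            f"cronbach_alpha needs >= 3 complete rows, got {complete.shape[0]}"
        )
    k = complete.shape[1]
    item_vars = complete.var(axis=0, ddof=0)
    total_var = complete.sum(axis=1).var(ddof=0)
    if total_var <= 0:
        raise DegenerateDataError("total score variance is zero")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
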