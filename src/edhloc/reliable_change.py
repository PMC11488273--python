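"""Jacobson–Truax reliable change and clinical significance.

The reliable change index (RCI) asks whether an individual's pre/post
difference exceeds what measurement error alone would produce:

    SE_m   = SD_admission * sqrt(1 - alpha)
    S_diff = sqrt(2) * SE_m
    threshold = z * S_diff          (z = 1.96 for 95% confidence)

Clinical significance uses criterion "c": the cutoff between clinical and
normative populations,

    c = (sd_norm * m_clinical + sd_clinical * m_norm) / (sd_norm + sd_clinical)

Crossing c from above marks movement into the normative range. Together the
two criteria classify each complete admission/follow-up pair into five
mutually exclusive groups: normative, deteriorated, unchanged, improved, and
clinically significant change. All scales here are higher-is-worse, and all
comparisons are strict (a change of exactly the threshold is not reliable).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scales import ScaleSpec, default_scale_registry

__all__ = [
    "ChangeCategory",
    "ChangeThresholds",
    "ChangeTable",
    "rci_threshold",
    "criterion_c_cutoff",
    "default_thresholds",
    "classify_change",
    "classify_pairs",
    "change_table",
]

DEFAULT_Z = 1.96


class ChangeCategory(enum.Enum):
    """Five-group Jacobson–Truax taxonomy.

    * ``normative`` — in the normative range at both timepoints
    * ``deteriorated`` — reliable worsening
    * ``unchanged`` — clinical at admission, no reliable change
    * ``improved`` — reliable improvement, still in the clinical range
    * ``clinically_significant`` — reliable improvement that crosses the
      clinical cutoff into the normative range
    """

    normative = "normative"
    deteriorated = "deteriorated"
    unchanged = "unchanged"
    improved = "improved"
    clinically_significant = "clinically_significant"


#: Report/column order used by the published-style change tables
#: (CSC, Reliable, Unchanged, Deteriorated, Normative).
CATEGORY_ORDER = [
    ChangeCategory.clinically_significant,
    ChangeCategory.improved,
    ChangeCategory.unchanged,
    ChangeCategory.deteriorated,
    ChangeCategory.normative,
]


@dataclass(frozen=True)
class ChangeThresholds:
    """Reliable-change threshold + clinical cutoff for one scale.

    ``rci_threshold`` is carried at full precision; reports round to two
    decimals but classification always compares at full precision.
    """

    scale: str
    rci_threshold: float
    cs_cutoff: float
    confidence_z: float = DEFAULT_Z
    provenance: str = "computed"

    def __post_init__(self) -> None:
        if self.rci_threshold < 0:
            raise ValidationError("rci_threshold must be non-negative")


def rci_threshold(admission_sd: float, alpha: float, z: float = DEFAULT_Z) -> float:
    """Reliable-change threshold z * sqrt(2) * sd * sqrt(1 - alpha).

    Returned at full precision; round to 2 decimals for reporting. With a
    perfectly reliable scale (alpha = 1) the threshold is 0.
    """
    if admission_sd <= 0:
        raise ValidationError("admission_sd must be positive")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("reliability alpha must lie in [0, 1]")
    if z <= 0:
        raise ValidationError("confidence multiplier z must be positive")
    se_m = admission_sd * math.sqrt(1.0 - alpha)
    return z * math.sqrt(2.0) * se_m


def criterion_c_cutoff(m_clinical: float, sd_clinical: float,
                       m_norm: float, sd_norm: float) -> float:
    """Criterion "c": SD-weighted mean of clinical and normative means."""
    if sd_clinical < 0 or sd_norm < 0:
        raise ValidationError("standard deviations must be non-negative")
    if sd_clinical == 0 and sd_norm == 0:
        raise ValidationError("at least one SD must be positive")
    return (sd_norm * m_clinical + sd_clinical * m_norm) / (sd_norm + sd_clinical)


def default_thresholds(registry: dict[str, ScaleSpec] | None = None,
                       z: float = DEFAULT_Z) -> dict[str, ChangeThresholds]:
    """Thresholds for every scale in the registry.

    RCI thresholds are computed from each scale's admission SD and
    reliability; clinical cutoffs come from the registry (they derive from
    adolescent community norms published elsewhere, so they are configured
    constants, not recomputed).
    """
    registry = registry or default_scale_registry()
    return {
        name: ChangeThresholds(
            scale=name,
            rci_threshold=rci_threshold(s.admission_sd, s.reliability_alpha, z),
            cs_cutoff=s.clinical_cutoff,
            confidence_z=z,
        )
        for name, s in registry.items()
    }


def classify_change(admit: float, followup: float,
                    thresholds: ChangeThresholds) -> ChangeCategory | None:
    """Classify one admission/follow-up pair (higher-is-worse scales).

    Missing either score returns ``None`` (unclassifiable; excluded from
    table denominators). Ties at the threshold or cutoff are not reliable
    change / range crossing (strict inequalities).

    Pairs that start in the normative range stay ``normative`` unless they
    worsen reliably, in which case they are ``deteriorated``.
    """
    if admit is None or followup is None:
        return None
    admit = float(admit)
    followup = float(followup)
    if math.isnan(admit) or math.isnan(followup):
        return None
    rci = thresholds.rci_threshold
    cutoff = thresholds.cs_cutoff
    improvement = admit - followup  # positive = improvement
    if admit > cutoff:
        if improvement > rci:
            if followup < cutoff:
                return ChangeCategory.clinically_significant
            return ChangeCategory.improved
        if -improvement > rci:
            return ChangeCategory.deteriorated
        return ChangeCategory.unchanged
    # admission already in the normative range
    if -improvement > rci and followup > cutoff:
        return ChangeCategory.deteriorated
    return ChangeCategory.normative


@dataclass(frozen=True)
class ChangeTable:
    """Category counts and percentages for one scale x interval."""

    scale: str
    interval: str
    counts: dict[ChangeCategory, int]
    n_reporting: int

    @property
    def percentages(self) -> dict[ChangeCategory, float]:
        return {c: 100.0 * n / self.n_reporting for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        row = {c.value: self.percentages[c] for c in CATEGORY_ORDER}
        row["n_reporting"] = self.n_reporting
        return pd.DataFrame([row], index=pd.Index([self.interval], name="interval"))


def classify_pairs(pairs: pd.DataFrame, thresholds: ChangeThresholds) -> pd.Series:
    """Classify a frame with columns ``admit`` and ``followup``."""
    return pd.Series(
        [classify_change(a, f, thresholds)
         for a, f in zip(pairs["admit"], pairs["followup"])],
        index=pairs.index, dtype=object,
    )


def change_table(pairs: pd.DataFrame, thresholds: ChangeThresholds,
                 interval: str = "admit_to_discharge") -> ChangeTable:
    """Cohort change table over complete pairs.

    ``pairs`` has one row per participant with columns ``admit`` and
    ``followup``; rows with either score missing drop out of the reporting
    denominator. The five category percentages partition the reporting
    sample (they sum to 100 up to rounding).
    """
    cats = classify_pairs(pairs, thresholds).dropna()
    if cats.empty:
        raise ValidationError("empty reporting sample: no complete score pairs")
    counts = {c: int((cats == c).sum()) for c in ChangeCategory}
    return ChangeTable(scale=thresholds.scale, interval=interval,
                       counts=counts, n_reporting=int(cats.size))
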