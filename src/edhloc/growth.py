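"""Percent of expected body weight (%EBW) from LMS growth references.

Expected body weight for a given sex and age comes from a growth reference
in the LMS parameterization (Box–Cox power L, median M, coefficient of
variation S); the value at standard-normal deviate z is

    M * (1 + L*S*z)^(1/L)        (L != 0)
    M * exp(S*z)                 (L == 0)

Two methods are supported:

* ``median-bmi`` (default): expected weight = median BMI-for-age x height^2,
  the standard recommendation for adolescents; requires height.
* ``weight-for-age``: expected weight = median weight-for-age; no height.

%EBW = 100 * observed / expected. Ages are handled in months internally and
linearly interpolated on the reference grid; no extrapolation is performed.

A synthetic LMS reference (smooth parametric curves over ages 8–20 y) is
provided so the pipeline and tests run without any external download; real
LMS CSVs load through the same :class:`GrowthReferenceTable` interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GrowthReferenceTable",
    "lms_value",
    "expected_body_weight",
    "percent_ebw",
    "synthetic_reference",
    "synthetic_median_height",
]

MEASURES = ("bmi_for_age", "weight_for_age")
SEXES = ("female", "male")


def lms_value(L: float, M: float, S: float, z: float = 0.0) -> float:
    """Measure value at standard-normal deviate ``z`` for LMS row (L, M, S)."""
    if M <= 0 or S <= 0:
        raise ValidationError("LMS requires M > 0 and S > 0")
    if abs(L) < 1e-8:
        return M * float(np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValidationError(f"z={z} outside the support of LMS(L={L}, S={S})")
    return M * base ** (1.0 / L)


@dataclass(frozen=True)
class GrowthReferenceTable:
    """Sex x age LMS rows for one or more measures.

    Backed by a DataFrame with columns
    ``measure, sex, age_months, L, M, S``; per (measure, sex) the age grid
    must be strictly increasing with positive M and S.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"measure", "sex", "age_months", "L", "M", "S"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"growth reference missing columns {sorted(missing)}")
        if (self.data["M"] <= 0).any() or (self.data["S"] <= 0).any():
            raise ValidationError("growth reference requires M > 0 and S > 0")
        for (measure, sex), grp in self.data.groupby(["measure", "sex"]):
            ages = grp["age_months"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValidationError(
                    f"age grid for ({measure}, {sex}) must be strictly increasing"
                )

    @classmethod
    def from_csv(cls, path) -> "GrowthReferenceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def age_range(self, measure: str, sex: str) -> tuple[float, float]:
        grp = self._rows(measure, sex)
        ages = grp["age_months"]
        return float(ages.min()), float(ages.max())

    def _rows(self, measure: str, sex: str) -> pd.DataFrame:
        grp = self.data[(self.data["measure"] == measure) & (self.data["sex"] == sex)]
        if grp.empty:
            raise ValidationError(f"no reference rows for ({measure}, {sex})")
        return grp.sort_values("age_months")

    def interpolate(self, measure: str, sex: str,
                    age_months: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``age_months``; no extrapolation."""
        grp = self._rows(measure, sex)
        ages = grp["age_months"].to_numpy(dtype=float)
        if not ages[0] <= age_months <= ages[-1]:
            raise ValidationError(
                f"age {age_months} months outside reference grid "
                f"[{ages[0]}, {ages[-1]}] for ({measure}, {sex})"
            )
        return tuple(
            float(np.interp(age_months, ages, grp[c].to_numpy(dtype=float)))
            for c in ("L", "M", "S")
        )


def expected_body_weight(sex: str, age_months: float,
                         table: GrowthReferenceTable,
                         height_m: float | None = None,
                         method: str = "median_bmi",
                         fallback_weight_for_age: bool = False) -> float:
    """Expected body weight in kg for sex and age.

    ``median_bmi`` uses median BMI-for-age x height^2 (kg); a missing height
    raises unless ``fallback_weight_for_age`` permits falling back to the
    weight-for-age median.
    """
    if method not in ("median_bmi", "weight_for_age"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "median_bmi":
        if height_m is None or (isinstance(height_m, float) and np.isnan(height_m)):
            if not fallback_weight_for_age:
                raise ValidationError("median_bmi method requires height")
            method = "weight_for_age"
        elif height_m <= 0:
            raise ValidationError("height must be positive")
    if method == "median_bmi":
        _, m_bmi, _ = table.interpolate("bmi_for_age", sex, age_months)
        return m_bmi * height_m ** 2
    _, m_wfa, _ = table.interpolate("weight_for_age", sex, age_months)
    return m_wfa


def percent_ebw(observed_kg: float, expected_kg: float) -> float:
    """100 * observed / expected; both weights must be positive."""
    if observed_kg <= 0 or expected_kg <= 0:
        raise ValidationError("weights must be positive")
    return 100.0 * observed_kg / expected_kg


# ---------------------------------------------------------------------------
# Synthetic reference fixture
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray, lo: float, hi: float, mid: float, scale: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-(x - mid) / scale))


def synthetic_median_height(sex: str, age_months) -> np.ndarray:
    """Smooth synthetic median height (m) used by the cohort generator."""
    a = np.asarray(age_months, dtype=float)
    if sex == "female":
        h = _logistic(a, 1.26, 1.635, 140.0, 16.0)
    else:
        h = _logistic(a, 1.27, 1.76, 160.0, 18.0)
    return h


def synthetic_reference(age_min_months: int = 96, age_max_months: int = 240,
                        step: int = 6) -> GrowthReferenceTable:
    """Synthetic LMS growth reference over ages 8–20 years.

    Smooth parametric median curves with magnitudes typical of adolescent
    growth references (median BMI rising from ~16 to ~22 kg/m^2, median
    weight from ~27 to ~60+ kg), constant skewness L = -1.5 and coefficient
    of variation rising slightly with age. This is a synthetic stand-in
    shipped so the pipeline needs no external reference file; it is not a
    national growth standard.
    """
    ages = np.arange(age_min_months, age_max_months + 1, step, dtype=float)
    rows = []
    for sex in SEXES:
        if sex == "female":
            m_bmi = _logistic(ages, 15.8, 21.8, 156.0, 30.0)
            m_wfa = _logistic(ages, 26.0, 58.0, 148.0, 22.0)
        else:
            m_bmi = _logistic(ages, 15.9, 22.6, 168.0, 32.0)
            m_wfa = _logistic(ages, 27.0, 68.0, 168.0, 24.0)
        s_bmi = 0.095 + 0.0001 * (ages - age_min_months)
        s_wfa = 0.14 + 0.0001 * (ages - age_min_months)
        for age, mb, sb, mw, sw in zip(ages, m_bmi, s_bmi, m_wfa, s_wfa):
            rows.append(("bmi_for_age", sex, age, -1.5, mb, sb))
            rows.append(("weight_for_age", sex, age, -1.2, mw, sw))
    frame = pd.DataFrame(rows, columns=["measure", "sex", "age_months", "L", "M", "S"])
    return GrowthReferenceTable(frame)
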