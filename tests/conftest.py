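import numpy as np
import pandas as pd
import pytest

from edhloc.cohort import (CohortConfig, CountTruth, OutcomeTruth,
                           generate_cohort, impose_missingness)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def recovery_config(n: int = 500) -> CohortConfig:
    """Model-faithful generator settings for parameter-recovery simulations.

    Latent Gaussian trajectories recorded directly (no measurement layer),
    counts generated for every participant, no injected count outliers or
    repeat episodes — the fitted models are exactly the generating models.
    """
    return CohortConfig(
        n_participants=n, include_items=False,
        n_count_outliers=0, second_episode_fraction=0.0,
        outcomes={
            "edeq_global": OutcomeTruth(
                intercept=3.62, slope_per_day=-0.015, sigma2_b=1.5, sigma2_e=1.0,
                slope_modifiers={"an_bp": -0.01, "comorbid": 0.01,
                                 "dx_BN": -0.02, "dx_OSFED_UFED": -0.01}),
            "phq9": OutcomeTruth(14.87, -0.05, 30.0, 20.0),
            "gad7": OutcomeTruth(12.93, -0.03, 20.0, 13.0),
        },
        counts={"binge_count": CountTruth(
            intercept=1.4, slope_per_day=-0.04, sigma2_b=0.5, theta=1.5,
            diagnoses=("AN-R", "AN-BP", "BN", "BED", "OSFED_UFED"))},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One medium default-condition cohort shared across tests (n=2000)."""
    cohort = generate_cohort(CohortConfig(n_participants=2000), seed=42)
    return impose_missingness(cohort, rng=np.random.default_rng(43))


@pytest.fixture(scope="session")
def complete_cohort():
    """Smaller complete (pre-missingness) cohort for structural checks."""
    return generate_cohort(CohortConfig(n_participants=400), seed=7)


@pytest.fixture
def toy_growth_table():
    from edhloc.growth import GrowthReferenceTable

    frame = pd.DataFrame({
        "measure": ["bmi_for_age"] * 2 + ["weight_for_age"] * 2,
        "sex": ["female"] * 4,
        "age_months": [120.0, 180.0, 120.0, 180.0],
        "L": [-1.0, -2.0, -1.0, -1.0],
        "M": [16.0, 20.0, 30.0, 50.0],
        "S": [0.10, 0.12, 0.14, 0.14],
    })
    return GrowthReferenceTable(frame)
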