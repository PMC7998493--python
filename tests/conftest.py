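import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from biovariation import (
    BiomarkerSpec,
    MeasurementTable,
    SyntheticSpec,
    default_cohort_spec,
    generate_cohort,
)


def single_biomarker_spec(
    icc: float,
    *,
    cv_t: float = 0.2,
    n_subjects: int = 44,
    n_visits: int = 3,
    seed: int = 0,
    lognormal: bool = True,
    name: str = "marker",
) -> SyntheticSpec:
    """Spec with one lognormal biomarker at a chosen true (log-scale) ICC.

    Fixes the within-subject log-variance via cv_t and sets the
    between-subject log-variance so that icc = s_b^2/(s_b^2 + s_w^2).
    """
    import math

    s_w2 = math.log(cv_t**2 + 1)
    s_b2 = icc / (1 - icc) * s_w2 if icc < 1 else 1.0
    cv_g = math.sqrt(math.expm1(s_b2))
    return SyntheticSpec(
        biomarkers={
            name: BiomarkerSpec(mu=100.0, cv_g=cv_g, cv_t=cv_t, lognormal=lognormal)
        },
        n_subjects=n_subjects,
        n_visits=n_visits,
        seed=seed,
    )


@pytest.fixture
def toy_table() -> MeasurementTable:
    """5 subjects x 3 visits, one handcrafted biomarker, one covariate."""
    rng = np.random.default_rng(42)
    subjects = np.repeat([f"S{i}" for i in range(1, 6)], 3)
    visits = np.tile([1, 2, 3], 5)
    base = np.repeat(rng.normal(10, 2, 5), 3)
    y = base + rng.normal(0, 0.5, 15)
    df = pd.DataFrame(
        {
            "subject": subjects,
            "visit": visits,
            "marker": np.abs(y) + 1,
            "bmi": np.repeat(rng.normal(22, 2, 5), 3),
        }
    )
    return MeasurementTable(
        data=df, biomarkers=["marker"], covariates=["bmi"], n_visits=3
    )


@pytest.fixture(scope="session")
def default_cohort() -> MeasurementTable:
    return generate_cohort(default_cohort_spec(seed=7))
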