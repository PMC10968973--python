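import numpy as np
import pandas as pd
import pytest

from sigreach.data_model import add_derived_columns
from sigreach.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized default synthetic cohort with derived columns, seeded."""
    cohort, truth = generate(GeneratorConfig(n_patients=8_000, seed=424242))
    return add_derived_columns(cohort), truth


@pytest.fixture
def tiny_cohort():
    """Hand-written 6-patient cohort covering both reach groups."""
    df = pd.DataFrame(
        {
            "topography_code": ["C187", "C209", "C180", "C182", "C186", "C184"],
            "age_years": [44, 52, 47, 61, 70, 39],
            "sex": ["female", "male", "male", "female", "male", "female"],
            "race_ethnicity": ["NH-White"] * 6,
            "stage": ["localized", "regional", "distant", "localized", "regional", "distant"],
            "year_dx": [2001, 2005, 2011, 2016, 2020, 2008],
            "survival_months": pd.array([12, 48, 6, 120, 30, 3], dtype="Int64"),
            "vital_status": ["alive", "dead", "dead", "alive", "dead", "dead"],
            "autopsy_only": [False] * 6,
        }
    )
    return add_derived_columns(df)


def brute_force_counts(cohort, factor):
    """Independent counting oracle: plain python loop over rows."""
    counts = {}
    for _, row in cohort.iterrows():
        if row["reach"] not in ("VISUALIZABLE", "REQUIRES_COLONOSCOPY"):
            continue
        lvl = row[factor]
        a, n = counts.get(lvl, (0, 0))
        counts[lvl] = (a + (row["reach"] == "VISUALIZABLE"), n + 1)
    return counts
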