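import numpy as np
import pandas as pd
import pytest

import gestmix as gx
from gestmix.selection import IMPUTE_COLUMNS


@pytest.fixture(scope="session")
def cohort():
    """Default-config synthetic cohort (144 cases / 1,082 controls)."""
    return gx.simulate(seed=1234)


@pytest.fixture(scope="session")
def adjusted(cohort):
    return gx.preprocess_table(cohort.observed, cohort.qc)


@pytest.fixture(scope="session")
def imputations(adjusted):
    cols = [c for c in IMPUTE_COLUMNS if c in adjusted.df.columns]
    return gx.impute(adjusted.df, M=3, bounds=adjusted.bounds, seed=7, columns=cols)


def make_complete_null_table(
    n_cases: int, n_controls: int, seed: int, metal_betas: dict | None = None
) -> pd.DataFrame:
    """Case-control table with ln-scale metals and covariates, no missing
    cells, case status from a logistic model (default: global null)."""
    from gestmix.cohort import generate_cohort
    from gestmix.specs import METALS, OutcomeModelSpec

    spec = OutcomeModelSpec(
        intercept=-2.5,
        metal_betas=metal_betas or {},
        covariate_betas={},
        n_cases=n_cases,
        n_controls=n_controls,
    )
    need = int(max(4000, 16 * (n_cases + n_controls)))
    coh = generate_cohort(outcome_spec=spec, seed=seed, n_source=need)
    df = coh.truth.copy()
    for m in METALS:
        df[m] = np.log(df[m])
    keep = ["case"] + METALS + [
        "sex",
        "birth_period",
        "parity",
        "education",
        "smoking",
        "mat_age",
        "seafood",
        "gest_age",
        "folate",
        "bmi",
    ]
    return df[keep].reset_index(drop=True)
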