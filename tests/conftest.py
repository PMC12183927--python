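import numpy as np
import pandas as pd
import pytest

import bbadkit as bk

SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study's size (33 A- / 69 A+), seed 0."""
    return bk.generate_cohort(bk.default_config(), seed=SEED)


@pytest.fixture(scope="session")
def labeled_cohort(default_cohort):
    return bk.label_cohort(default_cohort)


def make_cohort_df(n: int = 3, rng: np.random.Generator | None = None,
                   **overrides) -> pd.DataFrame:
    """A small valid cohort frame; columns can be overridden per test."""
    if rng is None:
        rng = np.random.default_rng(SEED)
    base = {
        "id": [f"P{i}" for i in range(n)],
        "age": rng.uniform(60, 85, n),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "education": rng.uniform(5, 18, n),
        "mmse": rng.uniform(15, 30, n),
        "apoe_e4": np.where(rng.random(n) < 0.4, "carrier", "noncarrier"),
        "diagnosis": np.where(rng.random(n) < 0.5, "MCI", "dementia"),
        "csf_ab42": rng.uniform(400, 1200, n),
        "csf_ab40": rng.uniform(6000, 18000, n),
        "csf_ttau": rng.uniform(200, 900, n),
        "csf_ptau181": rng.uniform(20, 180, n),
        "plasma_ab42": rng.uniform(15, 40, n),
        "plasma_ab40": rng.uniform(200, 500, n),
        "plasma_ptau181": rng.uniform(1, 5, n),
        "plasma_ptau217": rng.uniform(0.1, 1.5, n),
        "plasma_nfl": rng.uniform(10, 90, n),
    }
    base.update(overrides)
    return pd.DataFrame(base)


def build_labeled(n_neg: int, n_pos: int, rng: np.random.Generator,
                  **overrides) -> bk.CohortTable:
    """Labeled cohort with the first n_neg subjects A- and the rest A+.

    Group membership is imposed through the CSF Abeta42/40 ratio (A- around
    0.09, A+ around 0.05); any column can then be overridden to create a
    specific structure for a test.
    """
    n = n_neg + n_pos
    df = make_cohort_df(n, rng)
    ratio = np.concatenate([rng.normal(0.09, 0.005, n_neg),
                            rng.normal(0.05, 0.005, n_pos)])
    ratio = np.clip(ratio, 0.072, None)[:n_neg].tolist() + \
        np.clip(ratio[n_neg:], 0.01, 0.066).tolist()
    df["csf_ab40"] = 10000.0
    df["csf_ab42"] = np.asarray(ratio) * 10000.0
    for col, vals in overrides.items():
        df[col] = vals
    return bk.label_cohort(bk.CohortTable(df))
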