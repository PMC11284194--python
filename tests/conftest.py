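import numpy as np
import pandas as pd
import pytest

from aneumatch.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_matching_table(rows: list[dict]) -> pd.DataFrame:
    """Minimal case table for matching-layer tests.

    Only the matching features and stratification columns are populated;
    unspecified fields fall back to neutral values.
    """
    defaults = {
        "arm": "PA",
        "gender": "female",
        "age": 50.0,
        "ruptured": 0,
        "hunt_hess": None,
        "fisher_grade": None,
        "shape": "regular",
        "size_mm": 7.0,
        "fda_category": 1,
    }
    records = []
    for row in rows:
        rec = dict(defaults)
        rec.update(row)
        records.append(rec)
    df = pd.DataFrame(records)
    df["hunt_hess"] = df["hunt_hess"].astype("Int64")
    df["fisher_grade"] = df["fisher_grade"].astype("Int64")
    return df
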