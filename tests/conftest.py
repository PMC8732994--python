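import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from emodiv.cohort import ALL_SYMPTOMS, COHORT_COLUMNS, Cohort
from emodiv.items import ALL_ITEMS


def make_cohort_frame(
    n_chr: int = 5, n_hc: int = 5, seed: int = 0
) -> pd.DataFrame:
    """A small random, schema-valid cohort table."""
    rng = np.random.default_rng(seed)
    n = n_chr + n_hc
    rows = []
    for k in range(n):
        group = "CHR" if k < n_chr else "HC"
        row = {
            "id": f"{group}-{k:03d}",
            "group": group,
            "age": float(np.round(rng.uniform(14, 21), 2)),
            "sex": rng.choice(["male", "female"]),
            "parent_education": float(np.round(rng.uniform(10, 20), 2)),
            "antipsychotic": int(rng.random() < 0.2) if group == "CHR" else 0,
        }
        for item in ALL_ITEMS:
            row[item] = int(rng.integers(0, 5))
        for sym in ALL_SYMPTOMS:
            row[sym] = int(rng.integers(0, 7)) if group == "CHR" else int(
                rng.integers(0, 2)
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


@pytest.fixture
def cohort_frame() -> pd.DataFrame:
    return make_cohort_frame(n_chr=6, n_hc=6, seed=42)


@pytest.fixture
def cohort(cohort_frame) -> Cohort:
    return Cohort.from_frame(cohort_frame)
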