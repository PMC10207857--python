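"""Shared fixtures: the two-variable sex/localization toy table and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plauscheck import RecordTable, VariableSchema


@pytest.fixture
def toy_table() -> RecordTable:
    """Three tumor records over sex and localization.

    Record 0 (Male, Prostate) is the common case; records 1 (Female,
    Prostate) and 2 (Male, Breast) are the rare ones.
    """
    schema = [
        VariableSchema("sex", ("Male", "Female")),
        VariableSchema("localization", ("Prostate", "Breast")),
    ]
    data = pd.DataFrame(
        {
            "sex": ["Male", "Female", "Male"],
            "localization": ["Prostate", "Prostate", "Breast"],
        },
        dtype=str,
    )
    return RecordTable(schema, data)


def random_table(
    rng: np.random.Generator, n_rows: int, n_vars: int, max_domain: int = 4
) -> RecordTable:
    """Small random categorical table for oracle comparisons."""
    schema = []
    cols = {}
    for j in range(n_vars):
        size = int(rng.integers(2, max_domain + 1))
        domain = tuple(f"v{j}_{t}" for t in range(size))
        schema.append(VariableSchema(f"var{j}", domain))
        cols[f"var{j}"] = [domain[i] for i in rng.integers(0, size, size=n_rows)]
    return RecordTable(schema, pd.DataFrame(cols, dtype=str))
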