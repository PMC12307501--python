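import numpy as np
import pandas as pd
import pytest

from ahaging.core_data import AbundanceTable, CohortMetadata


def make_table(values, protein_ids=None, sample_ids=None) -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"P{i+1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i+1}" for i in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=protein_ids, columns=sample_ids))


def make_meta(ages, groups, sex=None, bmi=None, opacity=None, sample_ids=None) -> CohortMetadata:
    n = len(ages)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n)]
    return CohortMetadata(pd.DataFrame(
        {
            "age": ages,
            "sex": sex if sex is not None else [0] * n,
            "bmi": bmi if bmi is not None else [24.0] * n,
            "group": groups,
            "opacity_grade": opacity if opacity is not None else [np.nan] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_table():
    """3 proteins x 4 samples, no missing cells."""
    return make_table([[1.0, 2.0, 3.0, 4.0],
                       [5.0, 5.0, 6.0, 6.0],
                       [10.0, 8.0, 9.0, 7.0]])


@pytest.fixture
def toy_meta():
    return make_meta([70.0, 65.0, 25.0, 30.0],
                     ["older", "older", "young", "young"],
                     sex=[0, 1, 0, 1], bmi=[22.0, 25.0, 23.0, 26.0])
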