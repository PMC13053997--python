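import numpy as np
import pandas as pd
import pytest

from fittriage.data import AbundanceMatrix, case_control_labels
from fittriage.preprocess import run_preprocessing
from fittriage.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (141 samples 50/45/46, 334 proteins, seed 0)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def processed(default_cohort):
    matrix, sample_meta, protein_meta, truth = default_cohort
    return run_preprocessing(matrix, sample_meta, protein_meta)


@pytest.fixture(scope="session")
def sample_meta(default_cohort):
    return default_cohort[1]


@pytest.fixture(scope="session")
def ground_truth(default_cohort):
    return default_cohort[3]


@pytest.fixture(scope="session")
def binary_labels(default_cohort, processed):
    sm = default_cohort[1]
    return case_control_labels(sm.loc[processed["zscored"].sample_ids])


def make_matrix(values, scale_state="raw", protein_ids=None, sample_ids=None):
    """Small AbundanceMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    df = pd.DataFrame(
        values,
        index=protein_ids or [f"P{i+1:03d}" for i in range(p)],
        columns=sample_ids or [f"S{i+1:03d}" for i in range(n)],
    )
    return AbundanceMatrix.from_values(df, scale_state=scale_state)
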