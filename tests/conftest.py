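import numpy as np
import pandas as pd
import pytest

from bileflow.io_model import IntensityMatrix
from bileflow.synthetic_data import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    return generate_cohort(n_livers=20, n_proteins=120, n_markers=8, seed=11)


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        {
            "s1": [8.0, 2.0, 4.0],
            "s2": [16.0, np.nan, 1.0],
        },
        index=["pA", "pB", "pC"],
    )
    data.index.name = "protein"
    return IntensityMatrix(data, scale="raw")


def random_log2_matrix(rng, n_proteins=30, n_samples=10, prefix="s"):
    data = pd.DataFrame(
        rng.normal(20, 2, (n_proteins, n_samples)),
        index=[f"p{i}" for i in range(n_proteins)],
        columns=[f"{prefix}{j}" for j in range(n_samples)],
    )
    return IntensityMatrix(data, scale="log2")
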