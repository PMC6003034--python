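import numpy as np
import pandas as pd
import pytest

from arganet import datasets
from arganet.correlation import encode_dataset


@pytest.fixture(scope="session")
def study_samples():
    return datasets.study_samples()


@pytest.fixture(scope="session")
def fatty_acid_table() -> pd.DataFrame:
    return datasets.load_fatty_acids()


@pytest.fixture(scope="session")
def study_matrix(study_samples):
    """The 7 x 10 encoded study matrix (default variable encoding)."""
    return encode_dataset(study_samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
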