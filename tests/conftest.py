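import numpy as np
import pytest

from regenpath import datasets
from regenpath.scoring import default_classification_table
from regenpath.sem.fit import SampleMoments


@pytest.fixture(scope="session")
def model():
    return datasets.triticale_path_model()


@pytest.fixture(scope="session")
def moments():
    return datasets.triticale_moments()


@pytest.fixture(scope="session")
def truth():
    return datasets.triticale_truth()


@pytest.fixture(scope="session")
def table():
    return default_classification_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_pd_moments(rng, p, n=200):
    """Sample covariance of random correlated normal data (always PD)."""
    L = rng.normal(size=(p, p)) * 0.5 + np.eye(p)
    x = rng.normal(size=(n, p)) @ L.T
    return SampleMoments(
        S=np.cov(x, rowvar=False), n=n, variables=[f"v{i}" for i in range(p)]
    )
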