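import numpy as np
import pytest

from metafew import MetaDataset
from metafew.fixtures import (
    bbst_recovery_set,
    double_zero_set,
    simpson_set,
    single_zero_set,
    toy_k2,
    toy_k3,
)


@pytest.fixture
def k2():
    return toy_k2()


@pytest.fixture
def k3():
    return toy_k3()


@pytest.fixture
def with_single_zero():
    return single_zero_set()


@pytest.fixture
def with_double_zero():
    return double_zero_set()


@pytest.fixture
def simpson():
    return simpson_set()


@pytest.fixture(scope="session")
def recovery_bbst():
    return bbst_recovery_set(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


def swap_arms(dataset: MetaDataset) -> MetaDataset:
    """Exchange treatment and control arms of every study."""
    from metafew import StudyRecord

    return MetaDataset(
        [StudyRecord(s.study_id, s.y_c, s.n_c, s.y_t, s.n_t) for s in dataset.studies]
    )
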