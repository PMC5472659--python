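import numpy as np
import pytest

from nanoreadacross import SyntheticConfig, generate_dataset

ENDPOINT = "net_cell_association"


@pytest.fixture(scope="session")
def default_data():
    """Default synthetic dataset + ground truth (the study conditions)."""
    return generate_dataset(SyntheticConfig(seed=2024))


@pytest.fixture(scope="session")
def default_dataset(default_data):
    return default_data[0]


@pytest.fixture(scope="session")
def ground_truth(default_data):
    return default_data[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
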