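import numpy as np
import pytest

from neurogc.simulators import simulate


@pytest.fixture(scope="session")
def model_a_small():
    """A short model-A realization shared by fast unit tests."""
    return simulate("A", 600, seed=101)


@pytest.fixture(scope="session")
def model_a_long():
    """A full-length model-A realization for oracle-grade checks."""
    return simulate("A", 5000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
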