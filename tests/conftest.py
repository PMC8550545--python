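import numpy as np
import pytest

from multinomcheck import load_dataset


@pytest.fixture(scope="session")
def ccr5():
    return load_dataset("ccr5")


@pytest.fixture(scope="session")
def fly():
    return load_dataset("fly_diversity")


@pytest.fixture(scope="session")
def trine_sym():
    return load_dataset("trine_symmetric")


@pytest.fixture(scope="session")
def trine_asym():
    return load_dataset("trine_asymmetric")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
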