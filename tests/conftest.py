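import numpy as np
import pytest

from qsperceptron import (
    ReceiverSpec,
    default_registry,
    default_target_levels,
    make_set,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def receiver():
    return ReceiverSpec()


@pytest.fixture(scope="session")
def target_levels(receiver):
    return default_target_levels(receiver)


@pytest.fixture(scope="session")
def set3():
    return make_set(3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
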