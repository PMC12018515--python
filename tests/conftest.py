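import numpy as np
import pytest

from insulatk import connectivity, default_left_insula, default_right_insula, dynamics, somatotopy


@pytest.fixture
def right_insula():
    return default_right_insula()


@pytest.fixture
def left_insula():
    return default_left_insula()


@pytest.fixture
def ei_model():
    return dynamics.default_model()


@pytest.fixture
def regions():
    return somatotopy.packaged_regions()


@pytest.fixture
def conn():
    return connectivity.packaged_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20240923)
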