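import numpy as np
import pytest

from mguq.doe import ParameterSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_space_2d():
    return ParameterSpace([("x1", 0.0, 1.0), ("x2", 0.0, 1.0)])


@pytest.fixture
def box_space_2d():
    return ParameterSpace([("a", -2.0, 5.0), ("b", 1.0, 4.0)])
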