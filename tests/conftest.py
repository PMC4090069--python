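import numpy as np
import pytest

from netsym.core import WeightMatrix
from netsym.null_stats import NullModelSpec


@pytest.fixture
def hand_matrix() -> WeightMatrix:
    """3-neuron network with pair z values {0.5, 0.0} and one (0,0) pair.

    Pair (0,1): weights 0.6 / 0.2 -> z = 0.4/0.8 = 0.5
    Pair (0,2): weights 0.5 / 0.5 -> z = 0
    Pair (1,2): both zero -> excluded
    Hence s = 1 - (0.5 + 0)/2 = 0.75.
    """
    w = np.array(
        [
            [0.0, 0.6, 0.5],
            [0.2, 0.0, 0.0],
            [0.5, 0.0, 0.0],
        ]
    )
    return WeightMatrix(weights=w)


@pytest.fixture
def uniform_spec() -> NullModelSpec:
    return NullModelSpec(family="uniform")


@pytest.fixture
def gaussian_spec() -> NullModelSpec:
    return NullModelSpec(family="gaussian")
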