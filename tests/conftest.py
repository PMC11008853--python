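import numpy as np
import pytest

from dermakin import RateParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid_6h():
    """Standard chip sampling grid: 30 min samples over 6 h, plus t = 0."""
    return np.linspace(0.0, 6.0, 13)


def random_positive_params(rng, low=1e-2, high=1e2):
    return RateParameters.from_array(
        np.exp(rng.uniform(np.log(low), np.log(high), size=4))
    )
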