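import numpy as np
import pytest

from nurbsroc import Sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separated_sample():
    """Healthy values all below diseased values."""
    return Sample([1.0, 2.0, 3.0], [10.0, 11.0])


@pytest.fixture
def tiny_sample():
    """Fixed overlapping 5+5 sample used by optimizer oracles."""
    return Sample([0.2, 0.9, 1.4, 2.1, 3.0], [1.1, 1.8, 2.6, 3.3, 4.0])
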