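import numpy as np
import pytest

from rpmsim.diagnostics import equal_area_partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def partition100():
    """Default 10-band x 10-sector equal-area partition (100 cells)."""
    return equal_area_partition(10, 10)
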