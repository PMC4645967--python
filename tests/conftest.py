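import numpy as np
import pytest

from patchfuse import PhantomSpec, make_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom_pair():
    """The fixed-seed 128x128 pseudo-CT / pseudo-MR pair."""
    return make_phantom_pair(PhantomSpec(size=(128, 128), seed=0))
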