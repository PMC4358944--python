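import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20150313)


@pytest.fixture
def small_stack(rng):
    """Random 8-bit dual-channel stack small enough for loop oracles."""
    from airwayquant.io import DualChannelStack

    shape = (4, 8, 8)
    return DualChannelStack(
        green=rng.integers(0, 256, size=shape, dtype=np.uint8),
        red=rng.integers(0, 256, size=shape, dtype=np.uint8),
    )
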