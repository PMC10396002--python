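import numpy as np
import pytest

from icif import FusionConfig, SynthParams, make_pair


@pytest.fixture
def fast_config():
    """Small-radius configuration so pipeline tests stay quick."""
    return FusionConfig(radius=2, nf=16)


@pytest.fixture
def small_pair():
    """One deterministic 32x32 high-texture synthetic pair."""
    a, b, mask = make_pair(SynthParams(seed=11, size=(32, 32)))
    return a, b, mask


def random_intensity(rng, shape):
    """Random 8-bit-valued intensity image as float."""
    return rng.integers(0, 256, shape).astype(np.float64)
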