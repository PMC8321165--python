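import numpy as np
import pytest

from fibroseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_clean_phantom():
    """Noise-free, disease-free phantom; exactly segmentable by construction."""
    return generate_phantom(PhantomConfig(inplane=64, slices=24), seed=7)


@pytest.fixture(scope="session")
def small_severe_phantom():
    """Phantom with dense peripheral fibrosis above the region-growing window."""
    cfg = PhantomConfig(inplane=64, slices=24, severe_fraction=0.2)
    return generate_phantom(cfg, seed=8)
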