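import numpy as np
import pytest

import icdim


@pytest.fixture(scope="session")
def five_source_mixture():
    """Noiseless 20-channel mixture of 5 catalog sources, n=500."""
    src = icdim.simulate_sources(5, 500, seed=11)
    X, spec = icdim.mix_signals(src, 20, seed=2)
    return src, X, spec


@pytest.fixture(scope="session")
def eight_source_mixture():
    """Noiseless 30-channel mixture of the full 8-waveform catalog, n=512."""
    src = icdim.simulate_sources(8, 512, seed=1)
    X, spec = icdim.mix_signals(src, 30, seed=3)
    return src, X, spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
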