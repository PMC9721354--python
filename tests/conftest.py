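import numpy as np
import pytest

from cesynth.phantoms import PhantomParams
from cesynth.training import phantom_slice_pairs


@pytest.fixture(scope="session")
def tiny_pairs():
    """A small set of normalized 64x64 phantom slice pairs (shared)."""
    pairs, norm = phantom_slice_pairs(PhantomParams.tiny(seed=7), 8)
    return pairs, norm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
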