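import numpy as np
import pytest

from tigerreid import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 identities x 6 images at 64x128 - enough to exercise training."""
    return make_dataset(4, 6, size=(64, 128), seed=11)


def zero_weights(module):
    """Set every parameter of a module tree to zero (for closed-form gates)."""
    for p in module.parameters():
        p.data[...] = 0.0
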