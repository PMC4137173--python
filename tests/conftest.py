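import numpy as np
import pytest

from tectonic import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-participant RP-noise dataset with known ground truth."""
    spec = synth.DesignSpec(n_participants=2)
    return synth.make_dataset(7, "rp_noise", spec)


@pytest.fixture(scope="session")
def gaussian_dataset():
    """Two-participant Gaussian-noise dataset with known ground truth."""
    spec = synth.DesignSpec(n_participants=2)
    return synth.make_dataset(7, "gaussian", spec)
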