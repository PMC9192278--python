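import numpy as np
import pytest

from strokeseg.core import NoiseModel
from strokeseg.phantoms import add_lowdose_noise, default_spec, make_head_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One seeded 64x64 head phantom with a single lesion."""
    spec = default_spec(seed=11, shape=(64, 64), n_lesions=1)
    return make_head_phantom(spec)


@pytest.fixture(scope="session")
def noisy_pair(small_phantom):
    vol, _mask = small_phantom
    return add_lowdose_noise(vol, NoiseModel(sigma=25.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
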