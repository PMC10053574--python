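import numpy as np
import pytest

from xgifuse.config import SCMParams
from xgifuse.image_io import TriContrastSet
from xgifuse.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def phantom_small():
    """Noise-free 64x64 phantom shared by structural tests."""
    spec = PhantomSpec(shape=(64, 64), n_bodies=2,
                       noise_sigma_per_channel=(0.0, 0.0, 0.0), seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_default():
    """The default 256x256 noisy phantom."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture
def random_tri(rng):
    imgs = [rng.random((32, 32)) for _ in range(3)]
    return TriContrastSet(*imgs)


@pytest.fixture
def fast_scm():
    """Short SCM run for structural tests whose properties hold for any k."""
    return SCMParams(iterations=40)
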