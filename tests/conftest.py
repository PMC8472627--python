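import numpy as np
import pytest

from cascadereg.phantom import DeformationSpec, PhantomSpec, make_pair
from cascadereg.volume_io import LabelVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_spec():
    return PhantomSpec(grid_shape=(32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def small_case(small_phantom_spec):
    """One 32-cube registration case with a moderate ground-truth field."""
    return make_pair(small_phantom_spec, DeformationSpec(seed=3))


def random_volume(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    return Volume(rng.random(shape, dtype=np.float32), spacing)


def random_labels(rng, shape=(16, 16, 16), n_labels=3):
    return LabelVolume(rng.integers(0, n_labels + 1, size=shape,
                                    dtype=np.int32))
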