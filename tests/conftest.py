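import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from mousepet.grids import AnnotatedVolume, Grid

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")
from mousepet.phantom import PhantomSpec, make_reference_anatomy, render_modalities


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def anatomy(phantom_spec):
    return make_reference_anatomy(phantom_spec)


@pytest.fixture(scope="session")
def reference_modalities(anatomy, phantom_spec):
    """Noiseless (ct, mr, pet) renders of the reference anatomy."""
    return render_modalities(anatomy, phantom_spec)


@pytest.fixture(scope="session")
def phantom_atlas(anatomy):
    return anatomy.atlas()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_volume(shape=(10, 12, 14), spacing=0.2, seed=0, modality="CT"):
    g = np.random.default_rng(seed)
    grid = Grid(shape=shape, spacing=(spacing,) * 3, origin=(-1.0, 0.5, 2.0))
    return AnnotatedVolume(grid=grid, values=g.normal(size=shape), modality=modality)
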