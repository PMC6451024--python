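import numpy as np
import pytest

from glioradiomics.grids import TumorMask, VolumeImage
from glioradiomics.phantoms import PhantomSpec, generate_subject


@pytest.fixture(scope="session")
def gbm_subject():
    return generate_subject(PhantomSpec(class_label="glioblastoma", seed=42))


@pytest.fixture(scope="session")
def pcnsl_subject():
    return generate_subject(PhantomSpec(class_label="PCNSL", seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality="derived"):
    return VolumeImage(np.asarray(values, dtype=float), spacing, modality)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    return TumorMask(np.asarray(values) > 0, spacing)


@pytest.fixture
def ball_mask():
    """Spherical 9-voxel-radius mask inside a 24^3 grid."""
    g = np.indices((24, 24, 24))
    r2 = sum((x - 11.5) ** 2 for x in g)
    return make_mask(r2 <= 81)
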