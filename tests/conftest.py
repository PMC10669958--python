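import numpy as np
import pytest

from cariodet.geometry import BinaryMask, VoxelVolume
from cariodet.phantom import LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 3-tooth phantom at 0.5 mm with a distal lesion on the middle tooth."""
    spec = PhantomSpec(
        grid_shape=(48, 32, 48),
        spacing_mm=0.5,
        n_teeth=3,
        lesions=(LesionSpec(32, "distal", 25.0),),
        noise_sigma=0.02,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture
def gaussian_blob_volume():
    """Smooth blob phantom for interpolation round-trip checks."""
    shape = (40, 32, 32)
    spacing = (0.5, 0.5, 0.5)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    c = [n / 2 for n in shape]
    r2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    data = np.exp(-r2 / (2 * 6.0 ** 2)).astype(np.float32)
    return VoxelVolume(data, spacing)


def make_mask(shape, spacing, true_voxels):
    data = np.zeros(shape, bool)
    for v in true_voxels:
        data[v] = True
    return BinaryMask(data, spacing)
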