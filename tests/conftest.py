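import numpy as np
import pytest
from scipy import ndimage

from ehugs import ImageVolume, VelocityField


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_velocity(rng, shape, amplitude, smoothness=4.0):
    """Random smooth stationary velocity with a given sup amplitude."""
    v = rng.standard_normal((*shape, len(shape)))
    for k in range(len(shape)):
        v[..., k] = ndimage.gaussian_filter(v[..., k], smoothness)
    sup = np.sqrt((v * v).sum(axis=-1).max())
    if sup > 0:
        v *= amplitude / sup
    return VelocityField(v)


@pytest.fixture
def gaussian_blob_pair():
    """A Gaussian blob and the same blob translated by 2 voxels along axis 0."""
    x, y = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
    blob = np.exp(-((x - 24.0) ** 2 + (y - 24.0) ** 2) / 40.0)
    shifted = np.exp(-((x - 26.0) ** 2 + (y - 24.0) ** 2) / 40.0)
    return ImageVolume(blob, id="blob"), ImageVolume(shifted, id="blob_shifted")
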