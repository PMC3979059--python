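import numpy as np
import pytest

from bonemorph.roi import RoiMask, slab_mask
from bonemorph.volio import BinaryVolume, DensityVolume


@pytest.fixture
def full_roi():
    """ROI covering an entire volume."""

    def _make(vol) -> RoiMask:
        nz = vol.shape[0]
        return slab_mask(vol, range(0, nz), label="custom")

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data: np.ndarray, voxel_size_um: float = 6.0) -> DensityVolume:
    return DensityVolume(data=np.asarray(data, dtype=float), voxel_size_um=voxel_size_um)


def make_mask(mask: np.ndarray, voxel_size_um: float = 6.0) -> BinaryVolume:
    return BinaryVolume(mask=np.asarray(mask, dtype=bool), voxel_size_um=voxel_size_um)
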