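import numpy as np
import pytest

from lggspat import LabelVolume


def make_affine(spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def vol_from_indices(indices, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """LabelVolume with foreground exactly at the given voxel indices."""
    vox = np.zeros(shape, dtype=bool)
    for idx in indices:
        vox[tuple(idx)] = True
    return LabelVolume(vox, make_affine(spacing, origin))


def random_mask(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                max_voxels=50):
    """Non-empty random sparse mask."""
    n = int(rng.integers(1, max_voxels + 1))
    idx = np.column_stack([rng.integers(0, s, size=n) for s in shape])
    return vol_from_indices(idx, shape=shape, spacing=spacing, origin=origin)


def digitized_sphere(radius_mm, spacing=(1.0, 1.0, 1.0), center_mm=None, pad_voxels=2):
    """Sphere voxelized as 'voxel centers within radius of the center point'."""
    spacing = np.asarray(spacing, dtype=float)
    half = int(np.ceil(radius_mm / spacing.min())) + pad_voxels
    shape = (2 * half + 1,) * 3
    origin = -half * spacing
    if center_mm is None:
        center_mm = np.zeros(3)
    ax = [origin[k] + np.arange(shape[k]) * spacing[k] for k in range(3)]
    d2 = ((ax[0] - center_mm[0]) ** 2)[:, None, None] \
        + ((ax[1] - center_mm[1]) ** 2)[None, :, None] \
        + ((ax[2] - center_mm[2]) ** 2)[None, None, :]
    return LabelVolume(d2 <= radius_mm**2, make_affine(spacing, origin))


def brute_min_distance(a, b):
    """O(n*m) pairwise minimum voxel-center distance — the independent oracle."""
    wa = a.foreground_world()
    wb = b.foreground_world()
    diff = wa[:, None, :] - wb[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=2)).min())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
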