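"""Binary label volumes with world geometry.

A :class:`LabelVolume` is the atom of every computation in this package: a
3D boolean array together with the NIfTI affine that maps voxel indices to
world millimetres. All distances, volumes and centroids downstream are
computed in world units, so anisotropic voxels (thick clinical slices) are
handled correctly.

Masks are assumed to be already co-registered into a common space by an
upstream pipeline; this module validates shared grids but never resamples.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.affines import apply_affine

from .errors import DimensionalityError, EmptyMaskError, LggspatError

log = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "GridCheck",
    "read_label_volume",
    "write_label_volume",
    "check_grid_compatibility",
]


@dataclass(frozen=True)
class LabelVolume:
    """A binary 3D mask plus its voxel-to-world geometry.

    Parameters
    ----------
    voxels:
        3D boolean array; ``True`` is tumor foreground.
    affine:
        4x4 voxel-index -> world-mm map (NIfTI convention, RAS+).
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise DimensionalityError(
                f"label volume must be 3D, got {vox.ndim}D shape {vox.shape}"
            )
        if vox.dtype != bool:
            raise ValueError("LabelVolume.voxels must be boolean; use from_array()")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "affine", aff)
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @classmethod
    def from_array(cls, data: np.ndarray, affine: np.ndarray) -> "LabelVolume":
        """Build a volume from arbitrary numeric data.

        Any strictly nonzero finite voxel is foreground; NaNs are treated as
        background. A warning is logged when binarization actually changed
        values, since that usually means a probability map or a multi-label
        image was passed where a binary mask was expected.
        """
        arr = np.asarray(data)
        if np.issubdtype(arr.dtype, np.floating):
            nan = np.isnan(arr)
            if nan.all():
                raise LggspatError("volume data is all-NaN")
            if nan.any():
                log.warning("volume contains %d NaN voxels; treated as background", nan.sum())
                arr = np.where(nan, 0, arr)
        mask = arr != 0
        distinct = np.unique(arr[mask]) if mask.any() else np.array([])
        if distinct.size and not np.all(np.isin(distinct, [1])):
            log.warning(
                "volume contains values outside {0,1} (e.g. %s); binarized as nonzero=foreground",
                distinct[:5].tolist(),
            )
        return cls(voxels=mask, affine=affine)

    # -- derived geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per voxel-axis edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def foreground_indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of foreground, in raster order."""
        return np.argwhere(self.voxels)

    def foreground_world(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of foreground voxel centers."""
        idx = self.foreground_indices()
        if idx.size == 0:
            raise EmptyMaskError("mask has no foreground voxels")
        return apply_affine(self.affine, idx)

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        """A new volume on the same grid with different foreground."""
        return LabelVolume(voxels=np.asarray(voxels, dtype=bool), affine=self.affine)


@dataclass(frozen=True)
class GridCheck:
    """Diagnostic result of a grid-compatibility test."""

    ok: bool
    reason: str = field(default="")

    def __bool__(self) -> bool:
        return self.ok


def check_grid_compatibility(a: LabelVolume, b: LabelVolume, tol: float = 1e-3) -> GridCheck:
    """Verify two volumes live on the same voxel grid.

    Registration resampling leaves sub-micron float noise in affines, so
    equality is tested to ``tol`` mm per affine entry (default 1e-3); any
    larger discrepancy signals genuinely different spaces.
    """
    if a.shape != b.shape:
        return GridCheck(False, f"shape mismatch: {a.shape} vs {b.shape}")
    diff = float(np.abs(a.affine - b.affine).max())
    if diff > tol:
        return GridCheck(False, f"affine mismatch: max |delta| = {diff:g} mm > tol {tol:g} mm")
    return GridCheck(True)


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) binary mask.

    Foreground is every strictly nonzero voxel (see
    :meth:`LabelVolume.from_array`); affine and spacing come from the header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad files
        raise LggspatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    shape = img.shape
    if len(shape) != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got shape {shape}")
    data = np.asanyarray(img.dataobj)
    return LabelVolume.from_array(data, img.affine)


def write_label_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), volume.affine)
    nib.save(img, os.fspath(path))
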