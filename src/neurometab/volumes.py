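"""Gray-matter volume sets, the binary mask, and 3D <-> 1D index transforms.

Whole-brain statistics run on a subject x voxel matrix; the mask records the
bijection between 1D voxel ids (columns of that matrix) and 3D grid
coordinates so results can be written back into image space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, InputError


@dataclass
class GMVolumeSet:
    """Per-subject gray-matter probability volumes on a shared grid."""

    data: np.ndarray          # (n_subjects, nx, ny, nz), values in [0, 1]
    subjects: list[str]
    affine: np.ndarray        # shared voxel -> world transform

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise InputError("volume data must be (n_subjects, nx, ny, nz)")
        if len(self.subjects) != self.data.shape[0]:
            raise InputError("subject list does not match volume count")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def subset(self, subjects: list[str]) -> "GMVolumeSet":
        idx = [self.subjects.index(s) for s in subjects]
        return GMVolumeSet(self.data[idx], list(subjects), self.affine)


@dataclass
class GMMask:
    """Binary mask plus the bijective flat index over its True voxels.

    Voxel id ``j`` is the j-th True voxel in C order; ``coords[j]`` is its
    (i, j, k) grid coordinate and ``grid_indices[j]`` its flat index into the
    full grid, so ``volume[mask][j] == volume.ravel()[grid_indices[j]]``.
    """

    mask: np.ndarray          # boolean 3D
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.argwhere(self.mask)
        self.grid_indices = np.flatnonzero(self.mask.ravel())

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """3D volume -> 1D values over mask voxels (id order)."""
        if volume.shape != self.mask.shape:
            raise InputError("volume shape does not match mask")
        return volume[self.mask]

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """1D per-voxel values -> 3D volume (inverse transform)."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise InputError("value vector does not match mask voxel count")
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    def to_grid_ids(self, voxel_ids: np.ndarray) -> np.ndarray:
        """Mask-relative ids -> flat full-grid indices."""
        return self.grid_indices[np.asarray(voxel_ids, dtype=np.int64)]

    def from_grid_ids(self, grid_ids: np.ndarray) -> np.ndarray:
        """Flat full-grid indices -> mask-relative ids (must lie in mask)."""
        pos = np.searchsorted(self.grid_indices, grid_ids)
        if np.any(pos >= self.grid_indices.size) or np.any(
            self.grid_indices[np.clip(pos, 0, self.grid_indices.size - 1)] != grid_ids
        ):
            raise InputError("some grid indices fall outside the mask")
        return pos


def build_gm_mask(gm: GMVolumeSet, threshold: float = 0.3) -> GMMask:
    """Mask of voxels whose across-subject mean GM probability is >= threshold.

    The boundary value is included: the rule removes voxels with *less than*
    the threshold probability of being gray matter.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ConfigurationError("threshold must lie in [0, 1]")
    if gm.data.shape[0] < 1:
        raise InputError("at least one subject required")
    mean_map = gm.data.mean(axis=0)
    return GMMask(mask=mean_map >= threshold, affine=gm.affine)


def extract_voxel_matrix(gm: GMVolumeSet, mask: GMMask) -> np.ndarray:
    """Subject x voxel matrix of GM probabilities over the mask."""
    if gm.grid_dims != mask.mask.shape:
        raise InputError("mask and volumes have different grid shapes")
    return gm.data[:, mask.mask]


def save_mask(mask: GMMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine), str(path))


def save_voxel_map(mask: GMMask, values: np.ndarray, path: str | Path) -> None:
    """Write per-voxel statistics back to image space (inverse transform)."""
    vol = mask.unflatten(values, fill=0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))
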