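"""Volume geometry shared by every stage of the pipeline.

All maps live on a single reference grid (the analogue of the 2-mm
isotropic MNI space): a voxel array plus a 4x4 affine mapping integer
voxel indices to world millimetre coordinates.  No resampling is ever
performed — volumes entering a joint computation must share one grid.

Conventions
-----------
* 0-based integer voxel indices; world coordinates in mm.
* Voxel-center cells: continuous voxel coordinate ``x`` belongs to
  integer index ``i`` iff ``i - 0.5 <= x < i + 0.5`` per axis
  (half-open, so exact ``.5`` rounds up).
* Smoothing width is given as FWHM in mm, the neuroimaging convention;
  ``sigma = FWHM / (2 * sqrt(2 * ln 2))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "FWHM_PER_SIGMA",
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "world_to_voxel",
    "voxel_to_world",
    "nearest_voxel",
    "gaussian_smooth",
    "apply_mask",
    "mask_from_probability",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
]

#: FWHM = FWHM_PER_SIGMA * sigma for a Gaussian.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Two affines closer than this (max absolute difference) are the same grid.
AFFINE_TOL = 1e-6


class GridMismatchError(ValueError):
    """Volumes on different grids were combined."""


@dataclass(frozen=True)
class VolumeGrid:
    """Shape + affine of a voxel grid; the common space of all maps.

    Parameters
    ----------
    shape
        Number of voxels per axis, each >= 1.
    affine
        4x4 invertible matrix, ``world = affine @ [i, j, k, 1]``.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(affine)):
            raise ValueError("affine must be finite")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def compatible(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and bool(
            np.max(np.abs(self.affine - other.affine)) <= AFFINE_TOL
        )

    def voxel_to_world(self, points_vox: np.ndarray) -> np.ndarray:
        """Map continuous voxel coordinates (``(..., 3)``) to world mm."""
        return nib.affines.apply_affine(self.affine, np.asarray(points_vox, float))

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (``(..., 3)``) to continuous voxel space."""
        pts = np.asarray(points_mm, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("world coordinates must be finite")
        return nib.affines.apply_affine(self.inverse_affine, pts)

    def nearest_voxels(self, points_vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Round continuous voxel coordinates to integer indices.

        Returns ``(indices, in_grid)`` where ``indices`` has shape
        ``(n, 3)`` (valid only where ``in_grid``).  Rounding follows the
        half-open voxel-center cells ``[i - 0.5, i + 0.5)``.
        """
        pts = np.atleast_2d(np.asarray(points_vox, dtype=float))
        idx = np.floor(pts + 0.5).astype(np.int64)
        in_grid = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)
        return idx, in_grid

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)


def world_to_voxel(point_mm: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Continuous voxel coordinates of a world-mm point (round-trips with
    :func:`voxel_to_world` to better than 1e-9)."""
    return grid.world_to_voxel(point_mm)


def voxel_to_world(point_vox: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    return grid.voxel_to_world(point_vox)


def nearest_voxel(point_vox: np.ndarray, grid: VolumeGrid) -> tuple[int, int, int] | None:
    """Integer voxel index containing a continuous voxel coordinate.

    Returns ``None`` (the out-of-grid marker) when the rounded index
    falls outside the grid on any axis.
    """
    idx, in_grid = grid.nearest_voxels(np.asarray(point_vox, float).reshape(1, 3))
    if not in_grid[0]:
        return None
    return tuple(int(v) for v in idx[0])


def _check_same_grid(a: "ScalarVolume | BinaryMask", b: "ScalarVolume | BinaryMask") -> None:
    if not a.grid.compatible(b.grid):
        raise GridMismatchError(
            f"grids differ: shape {a.grid.shape} vs {b.grid.shape} "
            f"(or affines beyond {AFFINE_TOL})"
        )


@dataclass
class ScalarVolume:
    """A real-valued volume on a grid (GM image, atrophy map, ...)."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.data.copy())


@dataclass
class BinaryMask:
    """A {0,1} volume on a grid (lesion mask, GM mask, brain mask)."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {arr.shape} != grid shape {self.grid.shape}"
            )
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, got {uniq[:5]}")
        self.data = arr.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """``(n, 3)`` integer indices of the set voxels."""
        return np.argwhere(self.data > 0)

    def volume_ml(self) -> float:
        """Total mask volume in millilitres."""
        return float(self.n_voxels * np.prod(self.grid.voxel_size) / 1000.0)


def gaussian_smooth(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Separable Gaussian smoothing with an FWHM given in mm.

    Per-axis sigma (in voxels) is ``fwhm / (2 sqrt(2 ln 2) * voxel_size)``,
    so anisotropic voxels are handled.  The kernel is truncated at 4 sigma
    and the volume is zero-padded (no boundary renormalisation), which
    makes smoothing exactly linear and sum-conserving for interior signal.
    """
    if not np.isfinite(fwhm_mm) or fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = (fwhm_mm / FWHM_PER_SIGMA) / vol.grid.voxel_size
    out = ndimage.gaussian_filter(
        vol.data.astype(float), sigma=sigma_vox, mode="constant", cval=0.0, truncate=4.0
    )
    return ScalarVolume(vol.grid, out)


def apply_mask(vol: ScalarVolume, mask: BinaryMask) -> ScalarVolume:
    """Zero the volume outside the mask (idempotent)."""
    _check_same_grid(vol, mask)
    return ScalarVolume(vol.grid, vol.data * (mask.data > 0))


def mask_from_probability(vol: ScalarVolume, threshold: float = 0.5) -> BinaryMask:
    """Binarise a probabilistic template at ``value >= threshold``."""
    return BinaryMask(vol.grid, (vol.data >= threshold).astype(np.uint8))


# --------------------------------------------------------------------------
# NIfTI I/O.  Grids are taken from / written to the NIfTI affine; masks are
# stored as uint8, scalar maps as float32.

def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    if img.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    return VolumeGrid(tuple(int(s) for s in img.shape), np.asarray(img.affine))


def load_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(_grid_from_img(img), np.asanyarray(img.dataobj, dtype=float))


def load_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return BinaryMask(_grid_from_img(img), (data > 0.5).astype(np.uint8))


def save_volume(vol: ScalarVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.grid.affine)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
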