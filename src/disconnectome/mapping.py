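"""Disconnectome maps: from a lesion mask and a tractogram to a
gray-matter map of potential disconnection.

The chain (per subject): score every fiber by the number of lesion
voxels on its voxel path, add each fiber's score at its two endpoint
voxels, smooth the endpoint image with a Gaussian kernel (default
8 mm FWHM) and mask it to gray matter.

Because every step — scoring, endpoint accumulation, smoothing,
masking — is linear in the lesion indicator, the endpoint image a
single lesion voxel would generate can be precomputed for every voxel
any fiber passes through.  The disconnectome of an arbitrary lesion is
then the sum of those per-voxel contributions, smoothed and masked
once (:func:`fast_disconnectome`), and agrees with the direct
computation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .grid import (
    BinaryMask,
    GridMismatchError,
    ScalarVolume,
    VolumeGrid,
    apply_mask,
    gaussian_smooth,
)
from .tractogram import Tractogram

__all__ = [
    "DisconnectomeMap",
    "VoxelDisconnectomeIndex",
    "fiber_lesion_score",
    "fiber_lesion_scores",
    "endpoint_image",
    "disconnectome_map",
    "build_voxel_index",
    "fast_disconnectome",
    "endpoint_density",
]

DEFAULT_FWHM_MM = 8.0

INDEX_FORMAT_VERSION = 1


@dataclass
class DisconnectomeMap(ScalarVolume):
    """Smoothed, GM-masked endpoint-propagated lesion scores (>= 0)."""

    fwhm_mm: float = DEFAULT_FWHM_MM
    n_fibers: int = 0
    n_lesion_voxels: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.data < -1e-12):
            raise ValueError("disconnectome values must be non-negative")
        self.data = np.maximum(self.data, 0.0)


def _flat(idx: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)


def fiber_lesion_scores(t: Tractogram, lesion: BinaryMask) -> np.ndarray:
    """Per-fiber lesion overlap: number of distinct voxels on each
    fiber's path that belong to the lesion."""
    if not lesion.grid.compatible(t.reference_grid):
        raise GridMismatchError("lesion mask is not on the tractogram's grid")
    flat_lesion = lesion.data.ravel().astype(bool)
    shape = lesion.grid.shape
    scores = np.zeros(len(t), dtype=np.int64)
    for i, path in enumerate(t.voxel_paths()):
        if len(path):
            scores[i] = int(flat_lesion[_flat(path, shape)].sum())
    return scores


def fiber_lesion_score(s, lesion: BinaryMask, grid: VolumeGrid | None = None) -> int:
    """Lesion overlap count of a single streamline (see
    :func:`fiber_lesion_scores` for the whole-tractogram version)."""
    t = Tractogram([s], grid if grid is not None else lesion.grid)
    return int(fiber_lesion_scores(t, lesion)[0])


def endpoint_image(t: Tractogram, scores: np.ndarray) -> ScalarVolume:
    """Accumulate each fiber's score at its two endpoint voxels.

    Fibers scoring zero contribute nothing; out-of-grid endpoints are
    skipped.  When all endpoints are in-grid the image sums to
    ``2 * sum(scores)``.
    """
    scores = np.asarray(scores)
    if len(scores) != len(t):
        raise ValueError(f"{len(scores)} scores for {len(t)} fibers")
    grid = t.reference_grid
    data = np.zeros(grid.shape, dtype=float)
    ends = t.endpoint_voxels()  # (n, 2, 3), -1 marks out-of-grid
    nz = np.nonzero(scores > 0)[0]
    for which in (0, 1):
        e = ends[nz, which]
        ok = np.all(e >= 0, axis=1)
        if ok.any():
            np.add.at(data, (e[ok, 0], e[ok, 1], e[ok, 2]), scores[nz][ok].astype(float))
    return ScalarVolume(grid, data)


def disconnectome_map(
    lesion: BinaryMask,
    t: Tractogram,
    gm_mask: BinaryMask,
    fwhm_mm: float = DEFAULT_FWHM_MM,
) -> DisconnectomeMap:
    """Direct per-subject disconnectome: score fibers, project scores to
    endpoints, smooth (FWHM in mm), mask to gray matter."""
    if not gm_mask.grid.compatible(t.reference_grid):
        raise GridMismatchError("GM mask is not on the tractogram's grid")
    scores = fiber_lesion_scores(t, lesion)
    raw = endpoint_image(t, scores)
    out = apply_mask(gaussian_smooth(raw, fwhm_mm), gm_mask)
    return DisconnectomeMap(
        out.grid, out.data, fwhm_mm=fwhm_mm, n_fibers=len(t),
        n_lesion_voxels=lesion.n_voxels,
    )


@dataclass
class VoxelDisconnectomeIndex:
    """Sparse map from lesion voxel to the raw endpoint image it generates.

    ``matrix[v, e]`` counts, over all fibers whose voxel path contains
    flat voxel ``v``, the endpoints that fall in flat voxel ``e``
    (each in-grid endpoint of such a fiber contributes +1).  Rows of
    the matrix summed over a lesion's voxels give the raw (unsmoothed,
    unmasked) endpoint image of that lesion exactly.
    """

    grid: VolumeGrid
    matrix: sparse.csr_matrix  # (n_voxels, n_voxels) int64
    n_fibers: int

    def row_total(self, flat_voxel: int) -> int:
        return int(self.matrix[flat_voxel].sum())

    def save(self, path: str | Path) -> None:
        """Write the index as an .npz container (versioned)."""
        m = self.matrix.tocsr()
        np.savez_compressed(
            str(path),
            format_version=np.int64(INDEX_FORMAT_VERSION),
            data=m.data, indices=m.indices, indptr=m.indptr,
            matrix_shape=np.asarray(m.shape, dtype=np.int64),
            grid_shape=np.asarray(self.grid.shape, dtype=np.int64),
            affine=self.grid.affine,
            n_fibers=np.int64(self.n_fibers),
        )

    @classmethod
    def load(cls, path: str | Path) -> "VoxelDisconnectomeIndex":
        with np.load(str(path)) as z:
            if int(z["format_version"]) != INDEX_FORMAT_VERSION:
                raise ValueError(f"unsupported index version {int(z['format_version'])}")
            m = sparse.csr_matrix(
                (z["data"], z["indices"], z["indptr"]), shape=tuple(z["matrix_shape"])
            )
            grid = VolumeGrid(tuple(int(s) for s in z["grid_shape"]), z["affine"])
            return cls(grid, m, int(z["n_fibers"]))


def build_voxel_index(t: Tractogram) -> VoxelDisconnectomeIndex:
    """Precompute, for every voxel any fiber passes through, the raw
    endpoint image a lesion at exactly that voxel would generate."""
    if len(t) == 0:
        raise ValueError("empty tractogram")
    grid = t.reference_grid
    shape = grid.shape
    n = grid.n_voxels
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    ends = t.endpoint_voxels()
    for path, e in zip(t.voxel_paths(), ends):
        if len(path) == 0:
            continue
        pflat = _flat(path, shape)
        for which in (0, 1):
            if np.all(e[which] >= 0):
                eflat = int(np.ravel_multi_index(tuple(e[which]), shape))
                rows.append(pflat)
                cols.append(np.full(len(pflat), eflat, dtype=np.int64))
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        m = sparse.coo_matrix(
            (np.ones(len(r), dtype=np.int64), (r, c)), shape=(n, n)
        ).tocsr()
    else:
        m = sparse.csr_matrix((n, n), dtype=np.int64)
    return VoxelDisconnectomeIndex(grid, m, len(t))


def fast_disconnectome(
    lesion: BinaryMask,
    idx: VoxelDisconnectomeIndex,
    gm_mask: BinaryMask,
    fwhm_mm: float = DEFAULT_FWHM_MM,
) -> DisconnectomeMap:
    """Disconnectome via the per-voxel precomputation: sum the stored
    endpoint contributions over lesion voxels, then smooth and mask
    once.  Agrees with :func:`disconnectome_map` exactly (integer raw
    images, identical smoothing)."""
    if not idx.grid.compatible(lesion.grid):
        raise GridMismatchError("lesion mask is not on the index grid")
    lesion_flat = np.flatnonzero(lesion.data.ravel())
    if len(lesion_flat):
        raw_flat = np.asarray(idx.matrix[lesion_flat].sum(axis=0)).ravel().astype(float)
    else:
        raw_flat = np.zeros(idx.grid.n_voxels)
    raw = ScalarVolume(idx.grid, raw_flat.reshape(idx.grid.shape))
    out = apply_mask(gaussian_smooth(raw, fwhm_mm), gm_mask)
    return DisconnectomeMap(
        out.grid, out.data, fwhm_mm=fwhm_mm, n_fibers=idx.n_fibers,
        n_lesion_voxels=lesion.n_voxels,
    )


def endpoint_density(t: Tractogram) -> ScalarVolume:
    """Number of fiber endpoints per voxel (coverage map of the
    tractogram; sums to the number of in-grid endpoints)."""
    if len(t) == 0:
        raise ValueError("empty tractogram")
    grid = t.reference_grid
    data = np.zeros(grid.shape, dtype=float)
    ends = t.endpoint_voxels()
    for which in (0, 1):
        e = ends[:, which]
        ok = np.all(e >= 0, axis=1)
        if ok.any():
            np.add.at(data, (e[ok, 0], e[ok, 1], e[ok, 2]), 1.0)
    return ScalarVolume(grid, data)
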