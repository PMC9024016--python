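"""Streamlines and the discrete geometry that maps them onto voxels.

A streamline is an ordered polyline of world-mm points; its first and
last points are the anatomical endpoints.  Fibers are rasterised onto
the reference grid with the classic driving-axis 3D Bresenham line
(26-connected), the algorithm named for this step in lesion-network
mapping; a supercover variant is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .grid import VolumeGrid

__all__ = [
    "Streamline",
    "Tractogram",
    "segment_voxels",
    "segment_voxels_supercover",
    "streamline_voxel_path",
    "streamline_endpoint_voxels",
    "load_tractogram",
    "save_tractogram_text",
]

log = logging.getLogger(__name__)

Streamline = np.ndarray  # (n_points, 3) float array of world-mm points


def as_streamline(points: Sequence) -> Streamline:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
        raise ValueError(f"streamline must be (n>=1, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite points")
    return pts


def segment_voxels(a: Sequence[int], b: Sequence[int]) -> np.ndarray:
    """Classic driving-axis 3D Bresenham line between two voxel indices.

    Returns an ``(L, 3)`` int array starting at ``a`` and ending at
    ``b``.  Consecutive voxels differ by at most 1 per axis
    (26-connected), every axis is monotone along the path, and
    ``L = max_i |b_i - a_i| + 1`` (the Chebyshev distance plus one).
    Corner-touching voxels may be skipped; see
    :func:`segment_voxels_supercover` for the conservative variant.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    d = b - a
    step = np.sign(d)
    ad = np.abs(d)
    drive = int(np.argmax(ad))
    n = int(ad[drive])
    out = np.empty((n + 1, 3), dtype=np.int64)
    out[0] = a
    if n == 0:
        return out
    o1, o2 = [ax for ax in (0, 1, 2) if ax != drive]
    # error terms start at half the driving length so the line is
    # sampled at pixel centers
    err1 = 2 * ad[o1] - n
    err2 = 2 * ad[o2] - n
    x = a.copy()
    for i in range(1, n + 1):
        x[drive] += step[drive]
        if err1 > 0:
            x[o1] += step[o1]
            err1 -= 2 * n
        if err2 > 0:
            x[o2] += step[o2]
            err2 -= 2 * n
        err1 += 2 * ad[o1]
        err2 += 2 * ad[o2]
        out[i] = x
    return out


def segment_voxels_supercover(a: Sequence[int], b: Sequence[int]) -> np.ndarray:
    """All voxels whose cell the continuous segment between the two voxel
    centers intersects (6-connected traversal; never skips corners).

    Offered for sensitivity analyses; the default scoring path uses the
    classic Bresenham of :func:`segment_voxels`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # dense sampling at sub-voxel resolution, then dedup — adequate as a
    # reference implementation for integer-center segments
    n = max(2, int(np.ceil(np.max(np.abs(b - a)) * 8)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    idx = np.floor(pts + 0.5).astype(np.int64)
    return _dedup_rows(idx)


def _dedup_rows(rows: np.ndarray) -> np.ndarray:
    """Deduplicate (n, 3) integer rows keeping first occurrence order."""
    if len(rows) == 0:
        return rows.reshape(0, 3)
    view = np.ascontiguousarray(rows).view([("", rows.dtype)] * 3).ravel()
    _, first = np.unique(view, return_index=True)
    return rows[np.sort(first)]


def streamline_voxel_path(s: Streamline, grid: VolumeGrid) -> np.ndarray:
    """Ordered, duplicate-free voxel indices a fiber passes through.

    Every polyline point is rounded to its voxel; consecutive point
    voxels are joined by :func:`segment_voxels`; the concatenated path
    is deduplicated keeping first occurrences and clipped to the grid.
    A streamline entirely outside the grid yields an empty ``(0, 3)``
    array (warned, not an error).
    """
    s = as_streamline(s)
    pts_vox = grid.world_to_voxel(s)
    idx = np.floor(pts_vox + 0.5).astype(np.int64)
    if len(idx) == 1:
        segs = [idx]
    else:
        # drop consecutive duplicates before rasterising
        keep = np.ones(len(idx), dtype=bool)
        keep[1:] = np.any(idx[1:] != idx[:-1], axis=1)
        idx = idx[keep]
        segs = [segment_voxels(idx[i], idx[i + 1]) for i in range(len(idx) - 1)]
        if not segs:
            segs = [idx[:1]]
    path = _dedup_rows(np.concatenate(segs, axis=0))
    in_grid = grid.contains_index(path)
    path = path[in_grid]
    if len(path) == 0:
        log.warning("streamline lies entirely outside the grid")
    return path


def streamline_endpoint_voxels(
    s: Streamline, grid: VolumeGrid
) -> tuple[tuple[int, int, int] | None, tuple[int, int, int] | None]:
    """Voxel indices of the first and last polyline points (``None``
    marks an endpoint outside the field of view)."""
    s = as_streamline(s)
    ends = grid.world_to_voxel(s[[0, -1]])
    idx, in_grid = grid.nearest_voxels(ends)
    first = tuple(int(v) for v in idx[0]) if in_grid[0] else None
    last = tuple(int(v) for v in idx[1]) if in_grid[1] else None
    return first, last


@dataclass
class Tractogram:
    """A collection of streamlines referenced to a grid.

    Voxel paths and endpoint indices are computed lazily once per
    tractogram and cached; out-of-grid portions are clipped silently
    with a per-tractogram warning count (`n_clipped_warnings`).
    """

    streamlines: list[Streamline]
    reference_grid: VolumeGrid
    _paths: list[np.ndarray] | None = field(default=None, repr=False)
    _endpoints: np.ndarray | None = field(default=None, repr=False)
    n_clipped_warnings: int = 0

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def voxel_paths(self) -> list[np.ndarray]:
        """Cached per-fiber voxel paths (duplicate-free, in-grid)."""
        if self._paths is None:
            paths = []
            clipped = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for s in self.streamlines:
                    p = streamline_voxel_path(s, self.reference_grid)
                    if len(p) == 0:
                        clipped += 1
                    paths.append(p)
            self._paths = paths
            self.n_clipped_warnings = clipped
            if clipped:
                log.warning("%d streamlines fell entirely outside the grid", clipped)
        return self._paths

    def endpoint_voxels(self) -> np.ndarray:
        """``(n_fibers, 2, 3)`` int endpoint voxel indices; -1 marks an
        out-of-grid endpoint."""
        if self._endpoints is None:
            out = np.full((len(self.streamlines), 2, 3), -1, dtype=np.int64)
            for i, s in enumerate(self.streamlines):
                e0, e1 = streamline_endpoint_voxels(s, self.reference_grid)
                if e0 is not None:
                    out[i, 0] = e0
                if e1 is not None:
                    out[i, 1] = e1
            self._endpoints = out
        return self._endpoints


# --------------------------------------------------------------------------
# I/O.  TRK/TCK through nibabel (streamlines come back in world/RAS mm);
# plus a plain-text fixture format:
#
#     # comment lines start with '#'
#     n            <- number of points in the streamline
#     x y z        <- n lines of world-mm coordinates
#     ...          <- next streamline block
#

def load_tractogram(path: str | Path, grid: VolumeGrid) -> Tractogram:
    """Read a TRK, TCK or plain-text tractogram (world-mm streamlines)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".trk", ".tck"):
        tf = nib.streamlines.load(str(path))  # to_world applied by nibabel
        sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
        return Tractogram(sls, grid)
    if suffix in (".txt", ".tsl"):
        return Tractogram(_read_text_streamlines(path), grid)
    raise ValueError(f"unsupported tractogram format: {path.name}")


def _read_text_streamlines(path: Path) -> list[Streamline]:
    sls: list[Streamline] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        n = int(lines[i])
        if n < 1:
            raise ValueError(f"streamline block with n={n} in {path}")
        block = lines[i + 1 : i + 1 + n]
        if len(block) != n:
            raise ValueError(f"truncated streamline block in {path}")
        sls.append(np.array([[float(v) for v in ln.split()] for ln in block]))
        i += 1 + n
    return sls


def save_tractogram_text(t: Tractogram | Iterable[Streamline], path: str | Path) -> None:
    sls = t.streamlines if isinstance(t, Tractogram) else list(t)
    with open(path, "w") as fh:
        fh.write("# streamline text format v1: per block, 'n' then n lines 'x y z' (mm)\n")
        for s in sls:
            s = as_streamline(s)
            fh.write(f"{len(s)}\n")
            for p in s:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def save_tractogram_trk(t: Tractogram, path: str | Path) -> None:
    """Write a TRK file (streamlines kept in world/RAS mm)."""
    grid = t.reference_grid
    nt = nib.streamlines.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    header = {
        nib.streamlines.Field.VOXEL_TO_RASMM: grid.affine.copy(),
        nib.streamlines.Field.VOXEL_SIZES: tuple(grid.voxel_size),
        nib.streamlines.Field.DIMENSIONS: grid.shape,
    }
    nib.streamlines.save(nt, str(path), header=header)
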