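"""Voxel-wise association between disconnection and atrophy.

Across subjects, the per-voxel Pearson correlation between two map
collections (typically disconnectome vs atrophy) is computed inside an
analysis mask, optionally after residualizing both maps on a control
variable (lesion volume), with Benjamini–Hochberg FDR control over
the in-mask voxels.  Significance follows the strict rule of keeping
only FDR levels below alpha (q < alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .grid import BinaryMask, GridMismatchError, ScalarVolume, VolumeGrid

__all__ = [
    "CorrelationResult",
    "voxelwise_correlation",
    "voxelwise_partial_correlation",
    "fdr_correct",
    "region_max",
    "cohort_mean_map",
    "default_analysis_mask",
]

_P_FLOOR = np.finfo(float).tiny  # p-values live in (0, 1]


@dataclass
class CorrelationResult:
    """Per-voxel r / p / q and the q < alpha significance mask."""

    grid: VolumeGrid
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig: BinaryMask
    analysis_mask: BinaryMask
    n: int
    n_covariates: int
    alpha: float
    degenerate: np.ndarray = field(default=None)  # zero-variance voxels flagged

    @property
    def n_significant(self) -> int:
        return self.sig.n_voxels

    @property
    def significant_fraction(self) -> float:
        m = self.analysis_mask.n_voxels
        return self.sig.n_voxels / m if m else 0.0

    def r_volume(self) -> ScalarVolume:
        return ScalarVolume(self.grid, self.r)


def _stack(maps: Sequence[ScalarVolume]) -> tuple[np.ndarray, VolumeGrid]:
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.compatible(grid):
            raise GridMismatchError("maps are on different grids")
    return np.stack([m.data.ravel() for m in maps]), grid


def _pearson_columns(
    x: np.ndarray,
    y: np.ndarray,
    df: int,
    sx_floor: np.ndarray | float = 0.0,
    sy_floor: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, ...]:
    """Column-wise Pearson r and two-sided p (t transform, ``df`` d.o.f.).

    Columns where x or y has (numerically) zero variance — norm at or
    below the given floor — get r = 0, p = 1 and are flagged.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    degenerate = (sx <= sx_floor) | (sy <= sy_floor)
    denom = np.where(degenerate, 1.0, sx * sy)
    r = np.clip((xc * yc).sum(axis=0) / denom, -1.0, 1.0)
    r[degenerate] = 0.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, _P_FLOOR, 1.0)
    p[degenerate] = 1.0
    return r, p, degenerate


def _assemble(
    grid: VolumeGrid,
    mask: BinaryMask,
    flat_mask: np.ndarray,
    r_in: np.ndarray,
    p_in: np.ndarray,
    degenerate_in: np.ndarray,
    n: int,
    n_covariates: int,
    alpha: float,
) -> CorrelationResult:
    q_in, rej_in = fdr_correct(p_in, alpha)
    shape = grid.shape
    r = np.zeros(shape)
    p = np.ones(shape)
    q = np.ones(shape)
    sig = np.zeros(shape, dtype=np.uint8)
    deg = np.zeros(shape, dtype=bool)
    r.ravel()[flat_mask] = r_in
    p.ravel()[flat_mask] = p_in
    q.ravel()[flat_mask] = q_in
    sig.ravel()[flat_mask] = rej_in.astype(np.uint8)
    deg.ravel()[flat_mask] = degenerate_in
    return CorrelationResult(
        grid=grid, r=r, p=p, q=q,
        sig=BinaryMask(grid, sig), analysis_mask=mask,
        n=n, n_covariates=n_covariates, alpha=alpha, degenerate=deg,
    )


def voxelwise_correlation(
    x_maps: Sequence[ScalarVolume],
    y_maps: Sequence[ScalarVolume],
    mask: BinaryMask,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Per-voxel Pearson correlation of paired subject maps.

    Two-sided p-values come from the t transform with ``n - 2`` degrees
    of freedom; BH-FDR is applied over the in-mask voxels.
    """
    if len(x_maps) != len(y_maps):
        raise ValueError(f"unpaired collections: {len(x_maps)} vs {len(y_maps)}")
    n = len(x_maps)
    if n < 4:
        raise ValueError(f"need >= 4 subjects, got {n}")
    X, grid = _stack(x_maps)
    Y, _ = _stack(y_maps)
    if not mask.grid.compatible(grid):
        raise GridMismatchError("analysis mask is not on the map grid")
    flat_mask = np.flatnonzero(mask.data.ravel())
    r, p, degenerate = _pearson_columns(X[:, flat_mask], Y[:, flat_mask], n - 2)
    return _assemble(grid, mask, flat_mask, r, p, degenerate, n, 0, alpha)


def voxelwise_partial_correlation(
    x_maps: Sequence[ScalarVolume],
    y_maps: Sequence[ScalarVolume],
    covariate: np.ndarray,
    mask: BinaryMask,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlation controlled for one per-subject covariate.

    Both map stacks are residualized on ``[1, covariate]`` by least
    squares, then correlated; p-values use ``n - 3`` degrees of
    freedom.  A constant covariate reduces to the plain correlation
    (warned) with the partial degrees of freedom retained.
    """
    if len(x_maps) != len(y_maps):
        raise ValueError(f"unpaired collections: {len(x_maps)} vs {len(y_maps)}")
    n = len(x_maps)
    if n < 5:
        raise ValueError(f"need >= 5 subjects for a partial correlation, got {n}")
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (n,):
        raise ValueError(f"covariate must have length {n}")
    X, grid = _stack(x_maps)
    Y, _ = _stack(y_maps)
    if not mask.grid.compatible(grid):
        raise GridMismatchError("analysis mask is not on the map grid")
    flat_mask = np.flatnonzero(mask.data.ravel())

    if np.ptp(covariate) == 0:
        import warnings
        warnings.warn("constant control covariate: partial correlation "
                      "reduces to the plain correlation", stacklevel=2)
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack([np.ones(n), covariate])
    # residualize via the projection complement; exact least squares
    Q, _ = np.linalg.qr(Z)
    Xm = X[:, flat_mask]
    Ym = Y[:, flat_mask]
    Xr = Xm - Q @ (Q.T @ Xm)
    Yr = Ym - Q @ (Q.T @ Ym)
    # a map fully explained by the covariate leaves only rounding noise;
    # treat residual norms below 1e-10 of the original as zero variance
    sx_floor = 1e-10 * np.linalg.norm(Xm - Xm.mean(axis=0), axis=0)
    sy_floor = 1e-10 * np.linalg.norm(Ym - Ym.mean(axis=0), axis=0)
    r, p, degenerate = _pearson_columns(Xr, Yr, n - 3, sx_floor, sy_floor)
    return _assemble(grid, mask, flat_mask, r, p, degenerate, n, 1, alpha)


def fdr_correct(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg adjusted q-values and strict rejections.

    ``q_i = min_{j >= i} (m * p_(j) / j)`` capped at 1; rejection where
    ``q < alpha`` (only FDR levels strictly below alpha count as
    significant).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    reject = q < alpha
    return q, reject


def default_analysis_mask(
    gm_mask: BinaryMask,
    x_maps: Sequence[ScalarVolume],
    coverage: float = 0.9,
) -> BinaryMask:
    """GM voxels covered by the disconnection maps.

    Keeps GM voxels where at least ``coverage`` of subjects have a
    nonzero map value and the across-subject variance is nonzero, so
    the correlation is estimable there.
    """
    X, grid = _stack(x_maps)
    if not gm_mask.grid.compatible(grid):
        raise GridMismatchError("GM mask is not on the map grid")
    frac_nonzero = (X != 0).mean(axis=0)
    var = X.var(axis=0)
    keep = (gm_mask.data.ravel() > 0) & (frac_nonzero >= coverage) & (var > 0)
    return BinaryMask(grid, keep.reshape(grid.shape).astype(np.uint8))


def region_max(
    r_map: ScalarVolume,
    sig: BinaryMask,
    labels: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-region maximum r over significant voxels (atlas summary).

    One row per nonzero label in the label volume: the maximum r among
    significant voxels of the region, its peak voxel, and the
    significant-voxel count.  Regions without significant voxels are
    marked not-significant (NaN max_r).  Labels absent from the name
    table are reported as "unknown".
    """
    labels = np.asarray(labels)
    if labels.shape != r_map.grid.shape:
        raise GridMismatchError("label volume shape does not match the r map")
    if not sig.grid.compatible(r_map.grid):
        raise GridMismatchError("significance mask is not on the r-map grid")
    names = names or {}
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        in_region = labels == lab
        region_sig = in_region & (sig.data > 0)
        n_sig = int(region_sig.sum())
        if n_sig:
            r_vals = np.where(region_sig, r_map.data, -np.inf)
            peak = np.unravel_index(np.argmax(r_vals), r_map.grid.shape)
            max_r = float(r_map.data[peak])
        else:
            peak, max_r = (None, None, None), np.nan
        rows.append({
            "label": int(lab),
            "name": names.get(int(lab), "unknown"),
            "max_r": max_r,
            "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
            "n_sig_voxels": n_sig,
            "significant": bool(n_sig),
        })
    return pd.DataFrame(rows)


def cohort_mean_map(maps: Sequence[ScalarVolume]) -> ScalarVolume:
    """Voxel-wise arithmetic mean across subjects."""
    if not maps:
        raise ValueError("empty map collection")
    X, grid = _stack(maps)
    return ScalarVolume(grid, X.mean(axis=0).reshape(grid.shape))
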