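"""Normative gray-matter model and individual atrophy maps.

A voxel-wise linear model is fitted on healthy controls, predicting
the GM value at each voxel from age, sex and total intracranial
volume (TIV).  A subject's atrophy map is the difference
``predicted - observed``, so positive values mean less tissue than
the normative expectation.  Longitudinal change is handled by plain
subtraction of per-timepoint maps (images are assumed pre-aligned in
the common space).

Covariate coding: sex is 0/1 with female = 1; age in years; TIV in mL.
Covariates are mean-centered before the fit (conditioning only — the
stored means make predictions independent of centering).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import (
    BinaryMask,
    GridMismatchError,
    ScalarVolume,
    VolumeGrid,
    load_volume,
    save_volume,
)

__all__ = [
    "COVARIATE_COLUMNS",
    "NormativeModel",
    "fit_normative_model",
    "predict_gm",
    "atrophy_map",
    "lesion_increase",
    "map_increase",
    "read_covariates",
]

log = logging.getLogger(__name__)

#: Covariate CSV schema (sex: female=1/male=0; tiv in mL; volumes in mL).
COVARIATE_COLUMNS = [
    "subject_id", "age", "sex", "tiv", "group", "timepoint",
    "lesion_volume_ml", "new_lesion_volume_ml",
]

_COEF_NAMES = ("beta0", "beta_age", "beta_sex", "beta_tiv")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate table, validating the schema."""
    df = pd.read_csv(path)
    required = {"subject_id", "age", "sex", "tiv", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate CSV missing columns: {sorted(missing)}")
    if (df["age"] <= 0).any() or (df["tiv"] <= 0).any():
        raise ValueError("age and tiv must be positive")
    if not df["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded 0/1 (female=1)")
    return df


def _design_matrix(covariates: pd.DataFrame, means: np.ndarray) -> np.ndarray:
    X = np.column_stack([
        np.ones(len(covariates)),
        covariates["age"].to_numpy(float) - means[0],
        covariates["sex"].to_numpy(float) - means[1],
        covariates["tiv"].to_numpy(float) - means[2],
    ])
    return X


@dataclass
class NormativeModel:
    """Per-voxel OLS coefficients of GM on [1, age, sex, TIV] (centered)."""

    grid: VolumeGrid
    beta0: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    beta_tiv: np.ndarray
    covariate_means: np.ndarray  # (age, sex, tiv)
    n_controls: int

    def __post_init__(self) -> None:
        for name in _COEF_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)
        self.covariate_means = np.asarray(self.covariate_means, dtype=float)
        if self.n_controls < 5:
            raise ValueError("normative model requires >= 5 controls")

    # -- serialization: one NIfTI per coefficient + a JSON sidecar -------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in _COEF_NAMES:
            save_volume(ScalarVolume(self.grid, getattr(self, name)),
                        directory / f"{name}.nii.gz")
        meta = {
            "covariate_means": {"age": self.covariate_means[0],
                                "sex": self.covariate_means[1],
                                "tiv": self.covariate_means[2]},
            "n_controls": self.n_controls,
            "covariate_order": ["age", "sex", "tiv"],
            "sex_coding": "female=1, male=0",
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "NormativeModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        vols = {name: load_volume(directory / f"{name}.nii.gz") for name in _COEF_NAMES}
        grid = vols["beta0"].grid
        means = np.array([meta["covariate_means"][k] for k in ("age", "sex", "tiv")])
        return cls(grid, *(vols[n].data for n in _COEF_NAMES), means,
                   int(meta["n_controls"]))


def fit_normative_model(
    gm_volumes: Sequence[ScalarVolume],
    covariates: pd.DataFrame,
) -> NormativeModel:
    """Voxel-wise OLS of control GM on [1, age-mean, sex-mean, tiv-mean].

    Raises a ``ValueError`` naming the collinear column when the design
    is rank-deficient (for example, a single-sex control sample).
    """
    if len(gm_volumes) != len(covariates):
        raise ValueError(
            f"{len(gm_volumes)} volumes for {len(covariates)} covariate rows"
        )
    n = len(gm_volumes)
    if n < 5:
        raise ValueError(f"need >= 5 controls, got {n}")
    grid = gm_volumes[0].grid
    for v in gm_volumes[1:]:
        if not v.grid.compatible(grid):
            raise GridMismatchError("control volumes are on different grids")

    means = np.array([
        covariates["age"].to_numpy(float).mean(),
        covariates["sex"].to_numpy(float).mean(),
        covariates["tiv"].to_numpy(float).mean(),
    ])
    X = _design_matrix(covariates, means)
    # name the offending column rather than failing inside lstsq
    for j, name in enumerate(("age", "sex", "tiv"), start=1):
        if np.allclose(X[:, j], 0.0):
            raise ValueError(
                f"design is rank-deficient: covariate '{name}' is constant "
                "across controls"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank-deficient: covariates are collinear")

    Y = np.stack([v.data.ravel() for v in gm_volumes])  # (n, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)        # (4, V)
    coefs = [b.reshape(grid.shape) for b in beta]
    return NormativeModel(grid, *coefs, covariate_means=means, n_controls=n)


def predict_gm(model: NormativeModel, row: pd.Series | dict) -> ScalarVolume:
    """Expected GM volume for a subject's (age, sex, tiv)."""
    age, sex, tiv = float(row["age"]), float(row["sex"]), float(row["tiv"])
    m = model.covariate_means
    data = (
        model.beta0
        + model.beta_age * (age - m[0])
        + model.beta_sex * (sex - m[1])
        + model.beta_tiv * (tiv - m[2])
    )
    return ScalarVolume(model.grid, data)


def atrophy_map(
    model: NormativeModel, row: pd.Series | dict, observed: ScalarVolume
) -> ScalarVolume:
    """``predicted - observed``: positive where GM falls below the
    normative expectation.  Values above prediction stay negative
    (no clipping — clipping would bias downstream correlations)."""
    if not observed.grid.compatible(model.grid):
        raise GridMismatchError("observed GM volume is not on the model grid")
    predicted = predict_gm(model, row)
    return ScalarVolume(model.grid, predicted.data - observed.data)


def lesion_increase(l1: BinaryMask, l2: BinaryMask) -> BinaryMask:
    """New-lesion mask: voxels lesioned at timepoint 2 but not 1.

    The set difference never goes negative; voxels that disappear
    between timepoints are counted and logged, not subtracted.
    """
    if not l1.grid.compatible(l2.grid):
        raise GridMismatchError("lesion masks are on different grids")
    inc = (l2.data > 0) & (l1.data == 0)
    n_shrunk = int(((l1.data > 0) & (l2.data == 0)).sum())
    if n_shrunk:
        log.info("lesion_increase: %d voxels present at t1 vanished at t2", n_shrunk)
    return BinaryMask(l1.grid, inc.astype(np.uint8))


def map_increase(m1: ScalarVolume, m2: ScalarVolume) -> ScalarVolume:
    """Signed change map ``m2 - m1`` (no clipping)."""
    if not m1.grid.compatible(m2.grid):
        raise GridMismatchError("maps are on different grids")
    return ScalarVolume(m1.grid, m2.data - m1.data)
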