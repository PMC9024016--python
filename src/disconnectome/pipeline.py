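"""Orchestration of the study analyses over a dataset directory.

The two entry points mirror the study design:

* :func:`run_cross_sectional` — fit the normative model on controls,
  compute each patient's baseline disconnectome and atrophy map, and
  correlate them voxel-wise (plain and controlled for total lesion
  volume), with BH-FDR and an optional atlas region summary.
* :func:`run_longitudinal` — new-lesion masks (t2 minus t1) drive
  disconnection-increase maps, which are correlated with atrophy-
  increase maps (plain and controlled for new-lesion volume).

Both accept an in-memory :class:`StudyData` (e.g. straight from
``synthetic.simulate_cohort``) or a dataset directory written by
``synthetic.write_cohort``; results can be written to an output
directory with a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atrophy import (
    NormativeModel,
    atrophy_map,
    fit_normative_model,
    lesion_increase,
    map_increase,
    predict_gm,
    read_covariates,
)
from .grid import (
    BinaryMask,
    ScalarVolume,
    load_mask,
    load_volume,
    save_mask,
    save_volume,
)
from .mapping import build_voxel_index, endpoint_density, fast_disconnectome
from .stats import (
    CorrelationResult,
    cohort_mean_map,
    default_analysis_mask,
    region_max,
    voxelwise_correlation,
    voxelwise_partial_correlation,
)
from .synthetic import Cohort
from .tractogram import Tractogram, load_tractogram

__all__ = [
    "RunConfig",
    "StudyData",
    "AnalysisBundle",
    "load_study_data",
    "run_cross_sectional",
    "run_longitudinal",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable parameters of one analysis run."""

    dataset_dir: str = ""
    out_dir: str = ""
    fwhm_mm: float = 8.0
    alpha_fdr: float = 0.05
    coverage: float = 0.9
    gm_threshold: float = 0.5
    atrophy_mode: str = "absolute"  # or "percent" (of predicted GM)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyData:
    """Everything one analysis needs, already on a shared grid."""

    gm_mask: BinaryMask
    tractogram: Tractogram
    covariates: pd.DataFrame
    gm: dict                      # (subject_id, timepoint) -> ScalarVolume
    lesions: dict                 # (subject_id, timepoint) -> BinaryMask
    labels: np.ndarray | None = None
    label_names: dict | None = None

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "StudyData":
        return cls(
            gm_mask=cohort.phantom.gm_mask,
            tractogram=cohort.tractogram,
            covariates=cohort.covariates,
            gm=cohort.gm,
            lesions=cohort.lesions,
            labels=cohort.phantom.gm_labels,
            label_names={i: f"region_{i}" for i in
                         range(1, cohort.phantom.n_regions + 1)},
        )


def load_study_data(dataset_dir: str | Path) -> StudyData:
    """Load a dataset directory written by ``synthetic.write_cohort``
    (or any directory following the same layout)."""
    d = Path(dataset_dir)
    covariates = read_covariates(d / "covariates.csv")
    gm_mask = load_mask(d / "phantom" / "gm_mask.nii.gz")
    tractogram = load_tractogram(d / "tractogram.txt", gm_mask.grid)
    gm, lesions = {}, {}
    for _, row in covariates.iterrows():
        sid, tp = row["subject_id"], int(row["timepoint"])
        gm_path = d / "gm" / f"{sid}_t{tp}_gm.nii.gz"
        if gm_path.exists():
            gm[(sid, tp)] = load_volume(gm_path)
        lesion_path = d / "lesions" / f"{sid}_t{tp}_lesion.nii.gz"
        if lesion_path.exists():
            lesions[(sid, tp)] = load_mask(lesion_path)
    labels_path = d / "phantom" / "gm_labels.nii.gz"
    labels = None
    if labels_path.exists():
        labels = np.rint(load_volume(labels_path).data).astype(int)
    names = {i: f"region_{i}" for i in np.unique(labels)} if labels is not None else None
    return StudyData(gm_mask, tractogram, covariates, gm, lesions, labels, names)


@dataclass
class AnalysisBundle:
    """Result bundle of one analysis run."""

    model: NormativeModel
    subject_ids: list
    disconnectome_maps: list
    atrophy_maps: list
    analysis_mask: BinaryMask
    correlation: CorrelationResult
    correlation_controlled: CorrelationResult
    mean_atrophy: ScalarVolume
    endpoint_coverage: ScalarVolume
    region_table: pd.DataFrame | None
    manifest: dict


def _select(df: pd.DataFrame, **conds) -> pd.DataFrame:
    out = df
    for k, v in conds.items():
        out = out[out[k] == v]
    return out


def _patient_rows(data: StudyData, timepoint: int) -> pd.DataFrame:
    rows = _select(data.covariates, group="patient", timepoint=timepoint)
    with_lesions, dropped = [], []
    for _, row in rows.iterrows():
        key = (row["subject_id"], timepoint)
        if key in data.lesions and key in data.gm:
            with_lesions.append(row)
        else:
            dropped.append(row["subject_id"])
    if dropped:
        log.warning("excluding %d patients lacking images at t%d: %s",
                    len(dropped), timepoint, dropped)
    return pd.DataFrame(with_lesions)


def _atrophy(model, row, observed, mode: str) -> ScalarVolume:
    amap = atrophy_map(model, row, observed)
    if mode == "percent":
        pred = predict_gm(model, row).data
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(np.abs(pred) > 1e-6, 100.0 * amap.data / pred, 0.0)
        return ScalarVolume(amap.grid, pct)
    return amap


def _fit_model(data: StudyData, config: RunConfig) -> NormativeModel:
    controls = _select(data.covariates, group="control", timepoint=1)
    if controls.empty:
        raise ValueError("dataset contains no controls at timepoint 1")
    log.info("fitting normative model on %d controls", len(controls))
    vols = [data.gm[(r["subject_id"], 1)] for _, r in controls.iterrows()]
    return fit_normative_model(vols, controls)


def run_cross_sectional(
    data: StudyData | str | Path,
    config: RunConfig = RunConfig(),
) -> AnalysisBundle:
    """Baseline analysis: disconnectome vs atrophy across patients."""
    if not isinstance(data, StudyData):
        data = load_study_data(data)
    model = _fit_model(data, config)

    patients = _patient_rows(data, timepoint=1)
    if len(patients) < 4:
        raise ValueError(f"only {len(patients)} usable patients at timepoint 1")
    log.info("computing %d patient disconnectome + atrophy maps", len(patients))

    idx = build_voxel_index(data.tractogram)
    disc, atro, lesion_vol, sids = [], [], [], []
    for _, row in patients.iterrows():
        sid = row["subject_id"]
        lesion = data.lesions[(sid, 1)]
        disc.append(fast_disconnectome(lesion, idx, data.gm_mask, config.fwhm_mm))
        atro.append(_atrophy(model, row, data.gm[(sid, 1)], config.atrophy_mode))
        lv = row.get("lesion_volume_ml", np.nan)
        lesion_vol.append(lesion.volume_ml() if pd.isna(lv) else float(lv))
        sids.append(sid)

    mask = default_analysis_mask(data.gm_mask, disc, config.coverage)
    if mask.n_voxels == 0:
        log.warning("coverage mask is empty; falling back to the GM mask")
        mask = data.gm_mask
    corr = voxelwise_correlation(disc, atro, mask, config.alpha_fdr)
    corr_ctrl = voxelwise_partial_correlation(
        disc, atro, np.asarray(lesion_vol), mask, config.alpha_fdr
    )

    region_table = None
    if data.labels is not None:
        region_table = region_max(corr.r_volume(), corr.sig, data.labels,
                                  data.label_names)

    manifest = _manifest(config, "cross_sectional", len(patients), corr, mask,
                         n_controls=model.n_controls)
    return AnalysisBundle(
        model=model, subject_ids=sids, disconnectome_maps=disc,
        atrophy_maps=atro, analysis_mask=mask, correlation=corr,
        correlation_controlled=corr_ctrl,
        mean_atrophy=cohort_mean_map(atro),
        endpoint_coverage=endpoint_density(data.tractogram),
        region_table=region_table, manifest=manifest,
    )


def run_longitudinal(
    data: StudyData | str | Path,
    config: RunConfig = RunConfig(),
) -> AnalysisBundle:
    """Change analysis: disconnection increase vs atrophy increase."""
    if not isinstance(data, StudyData):
        data = load_study_data(data)
    model = _fit_model(data, config)

    p1 = _patient_rows(data, timepoint=1)
    p2 = _patient_rows(data, timepoint=2)
    both = sorted(set(p1["subject_id"]) & set(p2["subject_id"]))
    dropped = sorted(set(p1["subject_id"]) ^ set(p2["subject_id"]))
    if dropped:
        log.warning("dropping %d patients missing a timepoint: %s",
                    len(dropped), dropped)
    if len(both) < 4:
        raise ValueError(f"only {len(both)} patients have both timepoints")
    log.info("longitudinal analysis over %d patients", len(both))

    idx = build_voxel_index(data.tractogram)
    disc_inc, atro_inc, new_vol, sids = [], [], [], []
    for sid in both:
        r1 = p1[p1["subject_id"] == sid].iloc[0]
        r2 = p2[p2["subject_id"] == sid].iloc[0]
        inc_mask = lesion_increase(data.lesions[(sid, 1)], data.lesions[(sid, 2)])
        disc_inc.append(fast_disconnectome(inc_mask, idx, data.gm_mask,
                                           config.fwhm_mm))
        a1 = _atrophy(model, r1, data.gm[(sid, 1)], config.atrophy_mode)
        a2 = _atrophy(model, r2, data.gm[(sid, 2)], config.atrophy_mode)
        atro_inc.append(map_increase(a1, a2))
        nv = r2.get("new_lesion_volume_ml", np.nan)
        new_vol.append(inc_mask.volume_ml() if pd.isna(nv) else float(nv))
        sids.append(sid)

    mask = default_analysis_mask(data.gm_mask, disc_inc, config.coverage)
    if mask.n_voxels == 0:
        # degenerate family (e.g. no new lesions anywhere): keep the GM
        # mask so zero-variance voxels are reported as r=0 / p=1, flagged
        log.warning("no disconnection-increase coverage; reporting "
                    "degenerate correlations over the GM mask")
        mask = data.gm_mask
    corr = voxelwise_correlation(disc_inc, atro_inc, mask, config.alpha_fdr)
    corr_ctrl = voxelwise_partial_correlation(
        disc_inc, atro_inc, np.asarray(new_vol), mask, config.alpha_fdr
    )

    region_table = None
    if data.labels is not None:
        region_table = region_max(corr.r_volume(), corr.sig, data.labels,
                                  data.label_names)

    manifest = _manifest(config, "longitudinal", len(both), corr, mask,
                         n_controls=model.n_controls)
    return AnalysisBundle(
        model=model, subject_ids=sids, disconnectome_maps=disc_inc,
        atrophy_maps=atro_inc, analysis_mask=mask, correlation=corr,
        correlation_controlled=corr_ctrl,
        mean_atrophy=cohort_mean_map(atro_inc),
        endpoint_coverage=endpoint_density(data.tractogram),
        region_table=region_table, manifest=manifest,
    )


def _manifest(config: RunConfig, analysis: str, n_patients: int,
              corr: CorrelationResult, mask: BinaryMask, **extra) -> dict:
    return {
        "software": "disconnectome",
        "version": __version__,
        "analysis": analysis,
        "config": dataclasses.asdict(config),
        "n_patients": n_patients,
        "n_mask_voxels": mask.n_voxels,
        "n_significant": corr.n_significant,
        "alpha_fdr": corr.alpha,
        **extra,
    }


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> Path:
    """Write r/p/q/sig volumes, mean maps, region CSV and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corr = bundle.correlation
    grid = corr.grid
    save_volume(ScalarVolume(grid, corr.r), out / "r.nii.gz")
    save_volume(ScalarVolume(grid, corr.p), out / "p.nii.gz")
    save_volume(ScalarVolume(grid, corr.q), out / "q.nii.gz")
    save_mask(corr.sig, out / "sig.nii.gz")
    cc = bundle.correlation_controlled
    save_volume(ScalarVolume(grid, cc.r), out / "r_controlled.nii.gz")
    save_volume(ScalarVolume(grid, cc.q), out / "q_controlled.nii.gz")
    save_mask(cc.sig, out / "sig_controlled.nii.gz")
    save_mask(bundle.analysis_mask, out / "analysis_mask.nii.gz")
    save_volume(bundle.mean_atrophy, out / "mean_atrophy.nii.gz")
    save_volume(bundle.endpoint_coverage, out / "endpoint_density.nii.gz")
    if bundle.region_table is not None:
        bundle.region_table.to_csv(out / "region_table.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2,
                                                  sort_keys=True))
    return out
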