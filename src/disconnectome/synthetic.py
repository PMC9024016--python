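"""Seeded synthetic brain phantom, tractogram and cohorts with known truth.

The generator emulates, at desk scale, the data a lesion-disconnection
study consumes: a reference grid with gray-matter regions embedded in
white matter, a tractogram connecting a subset of those regions, focal
WM lesions, and control/patient GM images in which patient tissue loss
is injected *as a function of true disconnection*.  Every pipeline
stage can therefore be validated against ground truth without any
external data.

Generative model
----------------
* Controls: ``GM = template + b_age (age-40) + b_sex sex + b_tiv (tiv-1500) + noise``
  inside the brain mask, with i.i.d. Gaussian voxel noise.
* Patients: additionally ``- alpha * nd`` where ``nd`` is the subject's
  disconnectome map normalized by the cohort-wide maximum (so ``alpha``
  is the peak injected GM loss, in GM units).
* Longitudinal mode adds new lesions at timepoint 2 and the
  corresponding incremental connected-region loss; ages advance by the
  follow-up interval.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` substreams; the same seed reproduces the
cohort bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import (
    BinaryMask,
    ScalarVolume,
    VolumeGrid,
    gaussian_smooth,
    mask_from_probability,
    save_mask,
    save_volume,
)
from .mapping import build_voxel_index, fast_disconnectome
from .tractogram import Tractogram, save_tractogram_text

__all__ = [
    "PhantomConfig",
    "Phantom",
    "CohortParams",
    "GroundTruth",
    "Cohort",
    "DEFAULT_CONNECTIVITY",
    "make_phantom",
    "make_tractogram",
    "simulate_lesions",
    "simulate_cohort",
    "write_cohort",
]

log = logging.getLogger(__name__)

#: Region pairs (1-based labels) fibers connect by default: all pairs
#: among regions 1..6, so bundles crisscross the deep white matter the
#: way a whole-brain template does.  Two of the eight regions (7 and 8)
#: receive no fibers and act as negative controls for the voxel-wise
#: analyses.
DEFAULT_CONNECTIVITY: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(1, 7) for b in range(a + 1, 7)
)


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.0
    brain_radius_mm: float = 42.0
    n_regions: int = 8
    region_radius_mm: float = 8.0
    region_shell_radius_mm: float = 28.0
    center_jitter_mm: float = 1.5
    template_fwhm_mm: float = 4.0
    gm_threshold: float = 0.5


@dataclass
class Phantom:
    """Synthetic reference space: brain, GM regions, WM, GM template."""

    grid: VolumeGrid
    brain_mask: BinaryMask
    gm_labels: np.ndarray          # int, 0 = background, 1..K regions
    wm_mask: BinaryMask            # brain minus GM regions
    gm_template: ScalarVolume      # smooth probability in [0, 1]
    gm_mask: BinaryMask            # template >= threshold
    region_centers: np.ndarray     # (K, 3) world mm
    config: PhantomConfig

    @property
    def n_regions(self) -> int:
        return int(self.gm_labels.max())

    def region_voxels(self, label: int) -> np.ndarray:
        return np.argwhere(self.gm_labels == label)


def _sphere_directions(k: int) -> np.ndarray:
    """K well-separated unit vectors (cube vertices for K=8, otherwise a
    Fibonacci sphere)."""
    if k == 8:
        d = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                      for sz in (-1, 1)], dtype=float)
        return d / np.sqrt(3.0)
    i = np.arange(k, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / k
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_phantom(config: PhantomConfig = PhantomConfig(), seed: int = 0) -> Phantom:
    """Deterministic phantom: spherical brain with K disjoint GM regions
    on an inner shell, WM filling the remainder, and a smooth GM
    probability template peaking inside the regions.

    Raises ``ValueError`` if the configured regions cannot be placed
    disjointly (after the seeded center jitter).
    """
    c = config
    vs = float(c.voxel_size_mm)
    shape = tuple(int(s) for s in c.shape)
    # world origin at the volume center
    t = -vs * (np.asarray(shape) - 1) / 2.0
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = t
    grid = VolumeGrid(shape, affine)

    idx = np.indices(shape).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    dist0 = np.linalg.norm(world, axis=1)
    brain = (dist0 <= c.brain_radius_mm).reshape(shape)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0A]))
    centers = _sphere_directions(c.n_regions) * c.region_shell_radius_mm
    centers = centers + rng.uniform(-c.center_jitter_mm, c.center_jitter_mm,
                                    centers.shape)

    labels = np.zeros(shape, dtype=np.int32)
    claimed = np.zeros(shape, dtype=bool)
    for lab, center in enumerate(centers, start=1):
        d = np.linalg.norm(world - center, axis=1).reshape(shape)
        region = d <= c.region_radius_mm
        if np.any(region & claimed):
            raise ValueError(
                f"GM region {lab} overlaps an earlier region; reduce "
                "region_radius_mm or n_regions"
            )
        if not np.all(brain[region]):
            raise ValueError(f"GM region {lab} extends outside the brain mask")
        n_vox = int(region.sum())
        if n_vox < 30:
            raise ValueError(f"GM region {lab} has only {n_vox} voxels (< 30)")
        labels[region] = lab
        claimed |= region

    gm_binary = ScalarVolume(grid, (labels > 0).astype(float))
    template = gaussian_smooth(gm_binary, c.template_fwhm_mm)
    template = ScalarVolume(grid, np.clip(template.data, 0.0, 1.0))
    gm_mask = mask_from_probability(template, c.gm_threshold)
    wm = brain & (labels == 0)
    return Phantom(
        grid=grid,
        brain_mask=BinaryMask(grid, brain.astype(np.uint8)),
        gm_labels=labels,
        wm_mask=BinaryMask(grid, wm.astype(np.uint8)),
        gm_template=template,
        gm_mask=gm_mask,
        region_centers=centers,
        config=c,
    )


def make_tractogram(
    phantom: Phantom,
    connectivity: tuple[tuple[int, int], ...] = DEFAULT_CONNECTIVITY,
    n_fibers_per_pair: int = 200,
    jitter_sd_mm: float = 6.0,
    seed: int = 0,
    step_mm: float = 1.5,
) -> Tractogram:
    """Noisy polyline fibers between GM region pairs.

    Each fiber runs from a uniformly sampled voxel center in region A to
    one in region B along a quadratic Bezier curve whose midpoint
    control is jittered by ``N(0, jitter_sd_mm)`` per axis; with zero
    jitter the fiber is the straight segment between the sampled
    endpoints.  Endpoints therefore always lie inside their regions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7AC7]))
    labels = phantom.gm_labels
    streamlines = []
    for a, b in connectivity:
        vox_a = np.argwhere(labels == a)
        vox_b = np.argwhere(labels == b)
        if len(vox_a) == 0 or len(vox_b) == 0:
            raise ValueError(f"connectivity pair ({a}, {b}) names an empty region")
        for _ in range(n_fibers_per_pair):
            p0 = phantom.grid.voxel_to_world(vox_a[rng.integers(len(vox_a))])
            p1 = phantom.grid.voxel_to_world(vox_b[rng.integers(len(vox_b))])
            ctrl = (p0 + p1) / 2.0 + rng.normal(0.0, jitter_sd_mm, 3)
            chord = float(np.linalg.norm(p1 - p0))
            m = max(2, int(np.ceil(chord / step_mm)) + 1)
            t = np.linspace(0.0, 1.0, m)[:, None]
            pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1
            streamlines.append(pts)
    return Tractogram(streamlines, phantom.grid)


def simulate_lesions(
    phantom: Phantom,
    n_lesions_mean: float = 8.0,
    radius_median_mm: float = 3.0,
    radius_log_sd: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> BinaryMask:
    """Union of lognormal-radius spheres centered at uniformly sampled
    WM voxels, clipped to WM.  The lesion count is Poisson.

    Defaults give a total load around 1-2 mL on the ~360 mL phantom —
    the study-scale equivalent of a few mL of lesions on a full brain.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1E5]))
    wm_vox = phantom.wm_mask.indices()
    lesion = np.zeros(phantom.grid.shape, dtype=bool)
    n = int(rng.poisson(n_lesions_mean))
    if n == 0:
        return BinaryMask(phantom.grid, lesion.astype(np.uint8))
    centers_vox = wm_vox[rng.integers(len(wm_vox), size=n)]
    centers = phantom.grid.voxel_to_world(centers_vox)
    radii = np.exp(rng.normal(np.log(radius_median_mm), radius_log_sd, n))
    idx = np.indices(phantom.grid.shape).reshape(3, -1).T
    world = phantom.grid.voxel_to_world(idx)
    for center, r in zip(np.atleast_2d(centers), radii):
        d = np.linalg.norm(world - center, axis=1).reshape(phantom.grid.shape)
        lesion |= d <= r
    lesion &= phantom.wm_mask.data > 0
    return BinaryMask(phantom.grid, lesion.astype(np.uint8))


def expected_lesion_volume_ml(
    n_lesions_mean: float = 8.0,
    radius_median_mm: float = 3.0,
    radius_log_sd: float = 0.25,
) -> float:
    """Analytic Poisson x mean-sphere-volume product (mL), ignoring WM
    clipping and lesion overlap."""
    mu = np.log(radius_median_mm)
    e_r3 = np.exp(3 * mu + 4.5 * radius_log_sd**2)
    return float(n_lesions_mean * (4.0 / 3.0) * np.pi * e_r3 / 1000.0)


@dataclass(frozen=True)
class CohortParams:
    """Study conditions of the simulated cohorts.

    ``alpha`` is the peak injected GM loss (GM-probability units) at
    normalized disconnection 1; ``noise_sd`` the i.i.d. voxel noise of
    every scan.  The default ``alpha = 0.2`` is calibrated so that at
    the median affected voxel the across-patient scale of injected loss
    (about 0.05 in normalized-disconnection units) is half the scan
    noise, which puts the disconnection-atrophy coupling at the
    strongest deep-GM voxels near r ~ 0.7-0.8 — the effect-size regime
    lesion-disconnection studies report.  Lesions accrue at a constant
    rate of two per year (Poisson mean 8 at baseline, 12 more over the
    6-year follow-up).  Covariate
    effects and distributions mimic a plausible adult cohort (age
    uniform 20-60 y, female fraction 0.675, TIV normal 1500 +/- 120 mL).
    """

    alpha: float = 0.2
    noise_sd: float = 0.02
    #: Gamma shape of the per-patient severity multiplier (mean 1).
    #: Lesion counts are Gamma-Poisson mixed, giving the heavy-tailed
    #: lesion-load distribution real cohorts show (load CV well above
    #: the pure-Poisson value); the same multiplier scales new-lesion
    #: accrual, so active patients stay active.
    severity_shape: float = 0.7
    beta_age: float = -0.002    # GM units per year
    beta_sex: float = -0.01     # GM units, female vs male
    beta_tiv: float = 5.0e-5    # GM units per mL
    age_range: tuple[float, float] = (20.0, 60.0)
    female_fraction: float = 0.675
    tiv_mean_ml: float = 1500.0
    tiv_sd_ml: float = 120.0
    fwhm_mm: float = 8.0
    n_lesions_mean: float = 8.0
    new_lesions_mean: float = 12.0
    radius_median_mm: float = 3.0
    radius_log_sd: float = 0.25
    followup_years: float = 6.0
    #: A GM voxel counts as truly affected when at least
    #: ``affected_min_fraction`` of patients receive normalized loss
    #: above ``affected_threshold`` there (robust to the heavy-tailed
    #: severity distribution, where cohort means understate real loss).
    affected_threshold: float = 0.02
    affected_min_fraction: float = 0.1


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    params: CohortParams
    seed: int
    norm_constant: float                       # cohort max raw disconnectome
    nd_maps: dict                              # (subject_id, tp) -> float32 array
    affected_mask: BinaryMask                  # GM voxels with real injected loss
    affected_increase_mask: BinaryMask | None  # longitudinal counterpart


@dataclass
class Cohort:
    """In-memory synthetic dataset (see :func:`write_cohort` for disk)."""

    phantom: Phantom
    tractogram: Tractogram
    covariates: pd.DataFrame
    gm: dict                 # (subject_id, timepoint) -> ScalarVolume
    lesions: dict            # (subject_id, timepoint) -> BinaryMask (patients)
    truth: GroundTruth

    @property
    def patient_ids(self) -> list[str]:
        df = self.covariates
        return sorted(df.loc[df["group"] == "patient", "subject_id"].unique())

    @property
    def control_ids(self) -> list[str]:
        df = self.covariates
        return sorted(df.loc[df["group"] == "control", "subject_id"].unique())


def _clean_gm(phantom: Phantom, params: CohortParams, age, sex, tiv) -> np.ndarray:
    brain = phantom.brain_mask.data > 0
    effect = (
        params.beta_age * (age - 40.0)
        + params.beta_sex * sex
        + params.beta_tiv * (tiv - 1500.0)
    )
    return phantom.gm_template.data + effect * brain


def simulate_cohort(
    phantom: Phantom,
    tractogram: Tractogram,
    n_controls: int = 60,
    n_patients: int = 120,
    params: CohortParams = CohortParams(),
    longitudinal: bool = False,
    seed: int = 0,
) -> Cohort:
    """Generate control and patient cohorts with known ground truth.

    Patient GM images lose ``alpha * nd`` where ``nd`` is the subject's
    disconnectome (computed with the same engine the analysis uses)
    normalized by the maximum over all patients' baseline maps.  The
    "truly affected" mask marks GM voxels whose cohort-mean normalized
    loss exceeds ``params.affected_threshold``.
    """
    if n_controls < 10 or n_patients < 10:
        raise ValueError("need at least 10 controls and 10 patients")
    ss = np.random.SeedSequence([int(seed), 0xC0407])
    cov_rng, lesion_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    n_total = n_controls + n_patients
    age = cov_rng.uniform(*params.age_range, n_total)
    sex = (cov_rng.random(n_total) < params.female_fraction).astype(int)
    tiv = cov_rng.normal(params.tiv_mean_ml, params.tiv_sd_ml, n_total)
    if sex.min() == sex.max():  # degenerate draw: keep the design full rank
        sex[0] = 1 - sex[0]

    ids = [f"C{i + 1:03d}" for i in range(n_controls)] + [
        f"P{i + 1:03d}" for i in range(n_patients)
    ]
    groups = ["control"] * n_controls + ["patient"] * n_patients

    brain = phantom.brain_mask.data > 0
    grid = phantom.grid
    gm: dict = {}
    lesions: dict = {}
    rows = []

    # -- lesions and raw disconnectomes (two passes: normalization needs
    #    the cohort maximum first)
    idx = build_voxel_index(tractogram)
    disc: dict = {}
    severity = lesion_rng.gamma(params.severity_shape,
                                1.0 / params.severity_shape, n_patients)
    for i in range(n_patients):
        sid = ids[n_controls + i]
        l1 = simulate_lesions(
            phantom, severity[i] * params.n_lesions_mean,
            params.radius_median_mm, params.radius_log_sd, seed=lesion_rng,
        )
        lesions[(sid, 1)] = l1
        disc[(sid, 1)] = fast_disconnectome(l1, idx, phantom.gm_mask, params.fwhm_mm)
        if longitudinal:
            new = simulate_lesions(
                phantom, severity[i] * params.new_lesions_mean,
                params.radius_median_mm, params.radius_log_sd, seed=lesion_rng,
            )
            l2 = BinaryMask(grid, ((l1.data > 0) | (new.data > 0)).astype(np.uint8))
            lesions[(sid, 2)] = l2
            disc[(sid, 2)] = fast_disconnectome(l2, idx, phantom.gm_mask, params.fwhm_mm)

    t1_max = max(float(disc[(sid, 1)].data.max()) for sid in ids[n_controls:])
    norm = t1_max if t1_max > 0 else 1.0
    nd_maps = {k: (v.data / norm).astype(np.float32) for k, v in disc.items()}

    # -- GM images
    for i, sid in enumerate(ids):
        noise1 = noise_rng.normal(0.0, params.noise_sd, grid.shape) if params.noise_sd > 0 else 0.0
        clean1 = _clean_gm(phantom, params, age[i], sex[i], tiv[i])
        is_patient = groups[i] == "patient"
        loss1 = params.alpha * nd_maps[(sid, 1)] if is_patient else 0.0
        gm[(sid, 1)] = ScalarVolume(grid, (clean1 - loss1 + noise1 * brain))
        rows.append({
            "subject_id": sid, "age": age[i], "sex": sex[i], "tiv": tiv[i],
            "group": groups[i], "timepoint": 1,
            "lesion_volume_ml": lesions[(sid, 1)].volume_ml() if is_patient else np.nan,
            "new_lesion_volume_ml": np.nan,
        })
        if longitudinal and is_patient:
            age2 = age[i] + params.followup_years
            noise2 = noise_rng.normal(0.0, params.noise_sd, grid.shape) if params.noise_sd > 0 else 0.0
            clean2 = _clean_gm(phantom, params, age2, sex[i], tiv[i])
            loss2 = params.alpha * nd_maps[(sid, 2)]
            gm[(sid, 2)] = ScalarVolume(grid, (clean2 - loss2 + noise2 * brain))
            new_vol = lesions[(sid, 2)].volume_ml() - lesions[(sid, 1)].volume_ml()
            rows.append({
                "subject_id": sid, "age": age2, "sex": sex[i], "tiv": tiv[i],
                "group": "patient", "timepoint": 2,
                "lesion_volume_ml": lesions[(sid, 2)].volume_ml(),
                "new_lesion_volume_ml": new_vol,
            })

    covariates = pd.DataFrame(rows)

    # -- truth masks
    pat = ids[n_controls:]
    gm_bool = phantom.gm_mask.data > 0

    def _affected(loss_stack: np.ndarray) -> BinaryMask:
        frac = (loss_stack > params.affected_threshold).mean(axis=0)
        return BinaryMask(
            grid, ((frac >= params.affected_min_fraction) & gm_bool).astype(np.uint8)
        )

    affected_mask = _affected(np.stack([nd_maps[(sid, 1)] for sid in pat]))
    affected_increase = None
    if longitudinal:
        affected_increase = _affected(
            np.stack([nd_maps[(sid, 2)] - nd_maps[(sid, 1)] for sid in pat])
        )

    truth = GroundTruth(
        params=params, seed=int(seed), norm_constant=norm, nd_maps=nd_maps,
        affected_mask=affected_mask, affected_increase_mask=affected_increase,
    )
    return Cohort(phantom, tractogram, covariates, gm, lesions, truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort as a dataset directory (NIfTI + CSV + manifest)."""
    out = Path(out_dir)
    (out / "phantom").mkdir(parents=True, exist_ok=True)
    (out / "gm").mkdir(exist_ok=True)
    (out / "lesions").mkdir(exist_ok=True)

    ph = cohort.phantom
    save_mask(ph.brain_mask, out / "phantom" / "brain_mask.nii.gz")
    save_mask(ph.wm_mask, out / "phantom" / "wm_mask.nii.gz")
    save_mask(ph.gm_mask, out / "phantom" / "gm_mask.nii.gz")
    save_volume(ph.gm_template, out / "phantom" / "gm_template.nii.gz")
    save_volume(ScalarVolume(ph.grid, ph.gm_labels.astype(float)),
                out / "phantom" / "gm_labels.nii.gz")
    save_tractogram_text(cohort.tractogram, out / "tractogram.txt")
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    for (sid, tp), vol in cohort.gm.items():
        save_volume(vol, out / "gm" / f"{sid}_t{tp}_gm.nii.gz")
    for (sid, tp), mask in cohort.lesions.items():
        save_mask(mask, out / "lesions" / f"{sid}_t{tp}_lesion.nii.gz")

    t = cohort.truth
    save_mask(t.affected_mask, out / "truth_affected.nii.gz")
    if t.affected_increase_mask is not None:
        save_mask(t.affected_increase_mask, out / "truth_affected_increase.nii.gz")
    manifest = {
        "generator": "disconnectome.synthetic",
        "seed": t.seed,
        "norm_constant": t.norm_constant,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(t.params).items()},
        "n_controls": len(cohort.control_ids),
        "n_patients": len(cohort.patient_ids),
        "covariate_distributions": {
            "age": "uniform(20, 60) years",
            "sex": "Bernoulli(0.675), female=1",
            "tiv": "normal(1500, 120) mL",
        },
    }
    (out / "truth.json").write_text(json.dumps(manifest, indent=2))
    return out
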