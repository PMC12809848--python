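"""Synthetic resting-state fMRI cohort generator with known ground truth.

Builds a three-group cohort (healthy controls, treatment responders,
treatment-resistant patients) in which a designated DMN-like spatial source
carries a group-graded loading coefficient (HC < non-TRS < TRS) while the
marginal distribution of its time course is group-graded in the opposite
direction (heavier tails, hence lower histogram entropy, for patients).
Every downstream stage of the pipeline — motion quantification, nuisance
regression, group ICA, back-reconstruction, entropy and network-homogeneity
maps, and the group statistics — can therefore be validated against the
generator's ground truth without any external data.

The forward model per subject is the linear mixing model that group spatial
ICA assumes:

    image(v, t) = sum_k loading_k * map_k(v) * tc_k(t)
                  + wm/csf and motion leakage + Gaussian noise

with nonnegative multi-blob spatial sources and AR(1) time courses whose
marginal is a Student-t (a Gaussian scale mixture) when excess kurtosis is
requested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_LABELS = ("HC", "nonTRS", "TRS")

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "BoldRun",
    "build_source_maps",
    "simulate_timecourse",
    "assemble_bold",
    "simulate_phenotypes",
    "simulate_cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """All parameters of the synthetic cohort.

    Defaults emulate the study conditions: 64/76/48 subjects per group,
    235 retained volumes at TR = 2 s, a DMN-like source whose loading is
    group-graded upward and whose time-course kurtosis is group-graded
    upward (so its histogram entropy is graded downward).
    """

    group_sizes: tuple[int, int, int] = (64, 76, 48)
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_volumes: int = 235
    tr_s: float = 2.0
    n_sources: int = 3
    #: per-group mean loading of the DMN-like source (HC, nonTRS, TRS)
    loading_means: tuple[float, float, float] = (10.03, 10.15, 10.21)
    loading_sd: float = 0.28
    #: per-group excess kurtosis of the DMN time-course marginal
    entropy_kurtosis: tuple[float, float, float] = (0.0, 1.5, 4.0)
    ar_coeff: float = 0.4
    #: symptom units per unit loading (slope of the disorganization model)
    symptom_slope: float = 4.241
    symptom_noise_sd: float = 5.9
    noise_sd: float = 0.5
    #: scales the WM/CSF/motion leakage into voxel signals (0 = pure mixing)
    leak_scale: float = 1.0
    #: overall scale of simulated head motion (1.0 -> mean FD ~0.05-0.12 mm)
    motion_scale: float = 1.0
    sex_male_frac: tuple[float, float, float] = (0.41, 0.34, 0.54)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("group_sizes must be three integers, each >= 2")
        if self.n_volumes < 32:
            raise ValueError("n_volumes must be >= 32")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar_coeff) < 1:
            raise ValueError("ar_coeff must satisfy |ar_coeff| < 1")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def group_of(self) -> np.ndarray:
        """Group label per subject, HC block first."""
        return np.repeat(GROUP_LABELS, self.group_sizes)


@dataclass
class GroundTruth:
    """Generator ground truth used for parameter-recovery checks."""

    source_maps: np.ndarray  # (n_sources, *grid_shape), nonnegative, peak 1
    loadings: np.ndarray  # (n_subjects, n_sources)
    timecourses: np.ndarray  # (n_subjects, n_sources, n_volumes)
    dmn_index: int
    phenotypes: pd.DataFrame
    mask: np.ndarray  # (grid_shape) bool brain mask


@dataclass
class BoldRun:
    """One subject's 4D acquisition plus nuisance table and metadata."""

    image: np.ndarray  # (x, y, z, t)
    mask: np.ndarray  # (x, y, z) bool
    nuisance: pd.DataFrame  # t rows: trans_*, rot_*, wm, csf
    tr_s: float
    subject_id: str

    def __post_init__(self) -> None:
        if self.image.shape[-1] != len(self.nuisance):
            raise ValueError("nuisance row count must equal image time length")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")

    @property
    def motion(self) -> np.ndarray:
        cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        return self.nuisance[cols].to_numpy()


# ---------------------------------------------------------------------------
# spatial sources


def _ellipsoid_mask(grid_shape: Sequence[int]) -> np.ndarray:
    coords = np.indices(grid_shape).astype(float)
    center = (np.asarray(grid_shape, float) - 1.0) / 2.0
    semi = np.asarray(grid_shape, float) / 2.0 - 0.5
    d2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def _gaussian_blob(grid_shape: Sequence[int], center: np.ndarray, sigma: float) -> np.ndarray:
    coords = np.indices(grid_shape).astype(float)
    d2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
    return np.exp(-d2 / (2.0 * sigma**2))


def build_source_maps(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Place ``n_sources`` multi-blob nonnegative spatial sources on the grid.

    Source 0 is the DMN surrogate: a midline-anterior and a midline-posterior
    blob plus two lateral blobs, echoing the canonical default-mode topography.
    Remaining sources are 2-4 blobs at random centers kept far enough from all
    previously placed blobs that pairwise spatial correlation stays low.

    Returns an array of shape ``(n_sources, *grid_shape)`` with each map
    peak-normalized to 1.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1])
    gx, gy, gz = spec.grid_shape
    if min(spec.grid_shape) < 10:
        raise ValueError("grid too small: each axis must have >= 10 voxels")
    sigma = max(1.2, min(spec.grid_shape) / 12.0)
    mask = _ellipsoid_mask(spec.grid_shape)

    cx, cz = (gx - 1) / 2.0, (gz - 1) / 2.0
    dmn_centers = [
        np.array([cx, gy * 0.78, cz]),               # midline anterior
        np.array([cx, gy * 0.22, cz]),               # midline posterior
        np.array([gx * 0.22, gy * 0.40, gz * 0.62]),  # left lateral
        np.array([gx * 0.78, gy * 0.40, gz * 0.62]),  # right lateral
    ]
    placed = list(dmn_centers)
    all_centers: list[list[np.ndarray]] = [dmn_centers]

    # 5 sigma keeps blob clusters effectively disjoint (negligible overlap)
    min_dist = 5.0 * sigma
    for _ in range(1, spec.n_sources):
        n_blobs = int(rng.integers(2, 5))
        centers: list[np.ndarray] = []
        for _ in range(n_blobs):
            cand = None
            # relax separation gradually on crowded grids, floor at 4 sigma
            for dist in (min_dist, 4.5 * sigma, 4.0 * sigma):
                for _attempt in range(400):
                    trial = rng.uniform(
                        low=[gx * 0.12, gy * 0.12, gz * 0.12],
                        high=[gx * 0.88, gy * 0.88, gz * 0.88],
                    )
                    if all(np.linalg.norm(trial - c) >= dist for c in placed):
                        cand = trial
                        break
                if cand is not None:
                    break
            if cand is None:
                raise ValueError(
                    "grid too small to place the requested number of sources"
                )
            centers.append(cand)
            placed.append(cand)
        all_centers.append(centers)

    maps = np.zeros((spec.n_sources, gx, gy, gz))
    for k, centers in enumerate(all_centers):
        for c in centers:
            maps[k] += _gaussian_blob(spec.grid_shape, c, sigma)
        maps[k] *= mask
        maps[k] /= maps[k].max()
    return maps


# ---------------------------------------------------------------------------
# time courses


def simulate_timecourse(
    n_volumes: int,
    ar_coeff: float,
    excess_kurtosis: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """AR(1) time course with a controllable marginal excess kurtosis.

    The series is a Gaussian scale mixture x_t = s_t * g_t: g_t is a
    stationary Gaussian AR(1) process and s_t a slowly varying lognormal
    volatility process, s_t = exp(sigma_v * z_t) with z_t a persistent AR(1)
    (coefficient 0.9) of unit variance. Since s and g are independent, the
    marginal excess kurtosis is 3 * (E[s^4]/E[s^2]^2 - 1) = 3 * (e^{4 sigma_v^2} - 1),
    so sigma_v^2 = ln(1 + kurtosis/3) / 4 gives exactly the requested value
    in expectation. The slow volatility makes amplitude excursions persist
    over many samples, as BOLD variance fluctuations do, rather than
    appearing as isolated spikes.

    Returns a zero-mean, unit-variance series of length ``n_volumes``.
    """
    if not abs(ar_coeff) < 1:
        raise ValueError("ar_coeff must satisfy |ar_coeff| < 1 (stationarity)")
    if n_volumes < 32:
        raise ValueError("n_volumes must be >= 32")
    if excess_kurtosis < 0:
        raise ValueError("excess_kurtosis must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    burn = 50

    def _ar1(phi: float) -> np.ndarray:
        eps = rng.standard_normal(n_volumes + burn)
        y = np.empty(n_volumes + burn)
        y[0] = eps[0] / np.sqrt(1.0 - phi**2)
        for t in range(1, n_volumes + burn):
            y[t] = phi * y[t - 1] + eps[t]
        return y[burn:] * np.sqrt(1.0 - phi**2)  # unit marginal variance

    g = _ar1(ar_coeff)
    if excess_kurtosis > 0:
        sigma_v = np.sqrt(np.log1p(excess_kurtosis / 3.0) / 4.0)
        z = _ar1(0.9)
        x = np.exp(sigma_v * z) * g
    else:
        x = g
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


# ---------------------------------------------------------------------------
# subject assembly


def _simulate_motion(
    n_volumes: int, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Six rigid-body parameters as smooth random walks.

    ``scale`` = 1 yields mean Jenkinson FD in roughly the 0.05-0.12 mm band.
    Translations in mm, rotations in radians.
    """
    scale = scale * float(np.exp(rng.normal(0.0, 0.25)))  # between-subject spread
    step_t = 0.055 * scale  # mm per volume
    step_r = 0.00055 * scale  # rad per volume
    steps = np.hstack(
        [
            rng.standard_normal((n_volumes, 3)) * step_t,
            rng.standard_normal((n_volumes, 3)) * step_r,
        ]
    )
    walk = np.cumsum(steps, axis=0)
    # light smoothing keeps the walk drift-like rather than white
    kernel = np.array([0.25, 0.5, 0.25])
    for j in range(6):
        walk[:, j] = np.convolve(walk[:, j], kernel, mode="same")
    return walk


def _nuisance_signals(n_volumes: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    wm = simulate_timecourse(n_volumes, 0.5, 0.0, rng)
    csf = simulate_timecourse(n_volumes, 0.5, 0.0, rng)
    return wm, csf


def assemble_bold(
    ground_truth: GroundTruth,
    spec: CohortSpec,
    subject: int,
) -> BoldRun:
    """Mix one subject's sources into a 4D BOLD image plus nuisance table.

    image = sum_k loading_k * map_k (x) tc_k + wm/csf leakage
            + motion leakage + N(0, noise_sd).
    """
    n_subj = spec.n_subjects
    if not 0 <= subject < n_subj:
        raise ValueError(f"subject index {subject} outside cohort of {n_subj}")
    maps = ground_truth.source_maps
    if maps.shape[1:] != tuple(spec.grid_shape):
        raise ValueError("source map grid does not match spec grid_shape")

    rng = np.random.default_rng([spec.seed, 2, subject])
    T = spec.n_volumes
    group_idx = int(np.searchsorted(np.cumsum(spec.group_sizes), subject, side="right"))

    flat_maps = maps.reshape(spec.n_sources, -1)  # (K, V)
    tcs = ground_truth.timecourses[subject]  # (K, T)
    loadings = ground_truth.loadings[subject]  # (K,)
    data = (flat_maps.T * loadings) @ tcs  # (V, T)

    motion = _simulate_motion(T, spec.motion_scale * (1.0, 1.15, 1.3)[group_idx], rng)
    wm, csf = _nuisance_signals(T, rng)

    mask_flat = ground_truth.mask.reshape(-1)
    # global WM/CSF leakage into the brain plus one motion-driven pattern
    leak = spec.leak_scale
    data[mask_flat] += leak * (0.2 * wm + 0.15 * csf)
    motion_drive = motion / np.maximum(motion.std(axis=0), 1e-12)
    combined = motion_drive.sum(axis=1) / np.sqrt(6.0)
    leak_pattern = rng.uniform(0.0, 1.0, size=mask_flat.sum())
    data[mask_flat] += leak * 0.1 * np.outer(leak_pattern, combined)

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    image = data.reshape(*spec.grid_shape, T)
    nuisance = pd.DataFrame(
        np.hstack([motion, wm[:, None], csf[:, None]]),
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "wm", "csf"],
    )
    return BoldRun(
        image=image,
        mask=ground_truth.mask.copy(),
        nuisance=nuisance,
        tr_s=spec.tr_s,
        subject_id=f"sub-{subject:03d}",
    )


# ---------------------------------------------------------------------------
# phenotypes


_AGE_BY_GROUP = ((24.94, 2.97), (25.67, 7.41), (30.19, 8.77))
_EDU_BY_GROUP = ((16.03, 2.43), (13.30, 2.90), (13.10, 3.00))


def simulate_phenotypes(
    loadings_dmn: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-subject phenotype table with symptom linearly coupled to loading.

    disorganization = intercept + symptom_slope * loading + N(0, symptom_noise_sd);
    age and education carry group offsets mirroring the demographic ordering
    (patients younger-educated, the resistant group older).
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 3])
    groups = spec.group_of
    n = spec.n_subjects
    age = np.empty(n)
    edu = np.empty(n)
    sex = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(spec.group_sizes):
        sl = slice(start, start + size)
        age[sl] = np.clip(rng.normal(*_AGE_BY_GROUP[g], size=size), 18.0, None)
        edu[sl] = np.clip(rng.normal(*_EDU_BY_GROUP[g], size=size), 6.0, None)
        sex[sl] = rng.random(size) < spec.sex_male_frac[g]
        start += size
    intercept = -25.0  # centers symptoms near the clinical range at loading ~10
    symptom = (
        intercept
        + spec.symptom_slope * loadings_dmn
        + rng.normal(0.0, spec.symptom_noise_sd, size=n)
    )
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": groups,
            "age": age,
            "sex": sex,  # 1 = male
            "education_years": edu,
            "disorganization": symptom,
        }
    )


# ---------------------------------------------------------------------------
# cohort assembly and I/O


def simulate_cohort(spec: CohortSpec) -> tuple[GroundTruth, list[BoldRun]]:
    """Generate the full in-memory cohort: ground truth plus one run per subject."""
    maps = build_source_maps(spec)
    n = spec.n_subjects
    rng = np.random.default_rng([spec.seed, 0])
    groups = np.repeat(np.arange(3), spec.group_sizes)

    loadings = np.empty((n, spec.n_sources))
    tcs = np.empty((n, spec.n_sources, spec.n_volumes))
    other_mean = float(np.mean(spec.loading_means))
    for i in range(n):
        sub_rng = np.random.default_rng([spec.seed, 4, i])
        g = groups[i]
        for k in range(spec.n_sources):
            mean = spec.loading_means[g] if k == 0 else other_mean
            loadings[i, k] = sub_rng.normal(mean, spec.loading_sd)
            kurt = spec.entropy_kurtosis[g] if k == 0 else 0.0
            tcs[i, k] = simulate_timecourse(spec.n_volumes, spec.ar_coeff, kurt, sub_rng)

    gt = GroundTruth(
        source_maps=maps,
        loadings=loadings,
        timecourses=tcs,
        dmn_index=0,
        phenotypes=pd.DataFrame(),
        mask=_ellipsoid_mask(spec.grid_shape),
    )
    gt.phenotypes = simulate_phenotypes(loadings[:, 0], spec, np.random.default_rng([spec.seed, 3]))

    runs = [assemble_bold(gt, spec, i) for i in range(n)]
    # pairwise source-map independence check (generator contract)
    flat = maps.reshape(spec.n_sources, -1)
    if spec.n_sources > 1:
        cc = np.corrcoef(flat)
        off = np.abs(cc[~np.eye(spec.n_sources, dtype=bool)])
        if off.max() >= 0.5:
            warnings.warn(
                f"source maps unusually correlated (max |r| = {off.max():.2f})",
                stacklevel=2,
            )
    return gt, runs


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Write the cohort to disk and return a manifest of everything written.

    Layout: one 4D NIfTI and one nuisance TSV per subject, a phenotype TSV,
    a ground-truth ``.npz`` archive, and ``manifest.json`` listing all paths.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt, runs = simulate_cohort(spec)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    subjects = []
    for run in runs:
        img_path = out / f"{run.subject_id}_bold.nii"
        nui_path = out / f"{run.subject_id}_confounds.tsv"
        img = nib.Nifti1Image(run.image.astype(np.float32), affine)
        img.header.set_zooms((spec.voxel_size_mm,) * 3 + (spec.tr_s,))
        nib.save(img, img_path)
        run.nuisance.to_csv(nui_path, sep="\t", index=False, float_format="%.8g")
        subjects.append(
            {"subject_id": run.subject_id, "bold": img_path.name, "confounds": nui_path.name}
        )

    pheno_path = out / "phenotypes.tsv"
    gt.phenotypes.to_csv(pheno_path, sep="\t", index=False, float_format="%.8g")

    mask_path = out / "mask.nii"
    nib.save(nib.Nifti1Image(gt.mask.astype(np.uint8), affine), mask_path)

    gt_path = out / "ground_truth.npz"
    np.savez_compressed(
        gt_path,
        source_maps=gt.source_maps,
        loadings=gt.loadings,
        timecourses=gt.timecourses,
        dmn_index=gt.dmn_index,
        mask=gt.mask,
    )

    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(spec).items()
        },
        "tr_s": spec.tr_s,
        "subjects": subjects,
        "phenotypes": pheno_path.name,
        "mask": mask_path.name,
        "ground_truth": gt_path.name,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
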