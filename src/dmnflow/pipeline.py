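"""End-to-end orchestration: simulate/load -> preprocess -> gICA -> metrics -> stats.

``run_pipeline`` executes the full analysis on a cohort (simulated in memory
or loaded from a directory written by :func:`dmnflow.synthetic.generate_cohort`)
and writes a JSON run report, a per-subject metric table (TSV), and NIfTI
maps of the group components. Identical config + seed yields a byte-identical
metric table.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gica, metrics, preprocess, stats, synthetic
from .config import PipelineConfig

logger = logging.getLogger("dmnflow")

__all__ = ["run_pipeline", "load_cohort"]


def load_cohort(input_dir: str | Path):
    """Load a cohort directory written by ``generate_cohort``."""
    import nibabel as nib

    input_dir = Path(input_dir)
    with open(input_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    mask = np.asarray(nib.load(input_dir / manifest["mask"]).dataobj).astype(bool)
    runs = []
    for entry in manifest["subjects"]:
        img = np.asarray(nib.load(input_dir / entry["bold"]).dataobj, dtype=float)
        nui = pd.read_csv(input_dir / entry["confounds"], sep="\t")
        runs.append(
            synthetic.BoldRun(
                image=img, mask=mask, nuisance=nui,
                tr_s=float(manifest["tr_s"]), subject_id=entry["subject_id"],
            )
        )
    phenotypes = pd.read_csv(input_dir / manifest["phenotypes"], sep="\t")
    gt = None
    gt_path = input_dir / manifest.get("ground_truth", "")
    if gt_path.is_file():
        z = np.load(gt_path)
        gt = synthetic.GroundTruth(
            source_maps=z["source_maps"], loadings=z["loadings"],
            timecourses=z["timecourses"], dmn_index=int(z["dmn_index"]),
            phenotypes=phenotypes, mask=z["mask"].astype(bool),
        )
    return runs, phenotypes, gt


def _stage(report: dict, name: str, **params) -> None:
    report["stages"].append({"stage": name, "params": params})
    logger.info("stage %-12s %s", name, params)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(asdict(config)), "stages": [], "seed": config.seed}

    # --- stage A: data ----------------------------------------------------
    if config.input_dir is None:
        spec = synthetic.CohortSpec(seed=config.seed, **config.simulate)
        gt, runs = synthetic.simulate_cohort(spec)
        phenotypes = gt.phenotypes
        voxel_size = spec.voxel_size_mm
        _stage(report, "simulate", n_subjects=spec.n_subjects,
               grid=list(spec.grid_shape), n_volumes=spec.n_volumes, seed=spec.seed)
    else:
        runs, phenotypes, gt = load_cohort(config.input_dir)
        with open(Path(config.input_dir) / "manifest.json") as fh:
            voxel_size = float(json.load(fh)["spec"].get("voxel_size_mm", 3.0))
        _stage(report, "load", input_dir=str(config.input_dir), n_subjects=len(runs))

    # --- stage B: motion, exclusion, confounds ----------------------------
    fd_by_subject = {}
    confounds = {}
    for run in runs:
        fd = preprocess.framewise_displacement_jenkinson(run.motion)
        fd_by_subject[run.subject_id] = fd.mean_fd
        design24 = preprocess.expand_confounds_24(run.motion)
        wmcsf = run.nuisance[["wm", "csf"]].to_numpy()
        confounds[run.subject_id] = np.hstack([design24, wmcsf])
    retained_ids, exclusion_log = preprocess.apply_motion_exclusion(
        fd_by_subject, config.fd_threshold
    )
    runs = [r for r in runs if r.subject_id in retained_ids]
    phenotypes = phenotypes[phenotypes.subject_id.isin(retained_ids)].reset_index(drop=True)
    report["exclusion_log"] = exclusion_log
    _stage(report, "preprocess", fd_threshold=config.fd_threshold,
           retained=len(retained_ids))

    # --- stage C: group ICA ----------------------------------------------
    mask = runs[0].mask
    mask_flat = mask.reshape(-1)
    n_comp = config.n_components
    subject_mats = []
    for run in runs:
        smoothed = preprocess.gaussian_smooth(run.image, config.fwhm_mm, voxel_size)
        subject_mats.append(smoothed.reshape(-1, smoothed.shape[-1])[mask_flat].T)

    target = min(math.ceil(1.5 * n_comp), min(m.shape[0] for m in subject_mats))
    reduced = [gica.pca_reduce(m, target).reduced for m in subject_mats]
    group_mat, boundaries = gica.concat_group(reduced, [r.subject_id for r in runs])
    if config.n_runs >= 2:
        comps = gica.icasso_aggregate(
            group_mat, n_comp, n_runs=config.n_runs, seed=config.seed
        )
    else:
        res = gica.infomax_unmix(group_mat, n_comp, seed=config.seed)
        maps_z = np.array([gica.zscore_map(s) for s in res.sources])
        comps = gica.ComponentSet(
            spatial_maps=maps_z, group_timecourses=res.mixing,
            stability_iq=np.full(n_comp, np.nan), order=n_comp, run_count=1,
        )
    _stage(report, "gica", n_components=n_comp, n_runs=config.n_runs,
           iq=[None if np.isnan(q) else round(float(q), 4) for q in comps.stability_iq])

    # --- stage D: DMN identification and subject metrics ------------------
    if gt is not None:
        template = gica.zscore_map(
            gt.source_maps[gt.dmn_index].reshape(-1)[mask_flat]
        )
    else:
        raise ValueError(
            "no ground-truth template available; provide a simulated cohort "
            "or a template map (real-template input not configured)"
        )
    match = gica.match_template(comps.spatial_maps, template)
    dmn_idx = match.component_index
    _stage(report, "identify_dmn", component=dmn_idx,
           spatial_r=round(match.spatial_correlation, 4))

    rows = []
    for run, mat in zip(runs, subject_mats):
        subj = gica.back_reconstruct(mat.T, comps.spatial_maps)
        sc = subj[dmn_idx]
        tc_clean = preprocess.clean_component_timecourse(
            sc.timecourse, run.tr_s, confounds[run.subject_id],
            high_cutoff_hz=config.high_cutoff_hz,
        )
        ent = metrics.shannon_entropy(tc_clean, config.n_bins)
        rows.append(
            {"subject_id": run.subject_id, "loading": sc.loading,
             "entropy": ent.entropy_nats, "mean_fd": fd_by_subject[run.subject_id]}
        )
    metric_table = pd.DataFrame(rows).merge(phenotypes, on="subject_id")
    _stage(report, "metrics", n_bins=config.n_bins)

    # --- stage E: voxel-level NH (group mask from the DMN z-map) ----------
    dmn_map3d = np.zeros(mask.shape)
    dmn_map3d[mask] = comps.spatial_maps[dmn_idx]
    dmn_mask = (dmn_map3d >= config.mask_z_threshold) & mask
    nh_z_stack = None
    if dmn_mask.sum() >= 2:
        nh_rows = []
        for run in runs:
            cleaned = preprocess.clean_voxel_timeseries(
                run.image, run.tr_s, confounds[run.subject_id],
                band_hz=config.band_hz, mask=mask,
            )
            nh = metrics.network_homogeneity_map(cleaned, dmn_mask)
            zsm = preprocess.gaussian_smooth(nh.z, config.fwhm_mm, voxel_size)
            nh_rows.append(zsm[dmn_mask])
        nh_z_stack = np.array(nh_rows)  # (N, m)
        metric_table["mean_nh_z"] = nh_z_stack.mean(axis=1)
    _stage(report, "voxel_metrics", dmn_mask_voxels=int(dmn_mask.sum()),
           z_threshold=config.mask_z_threshold)

    # --- stage F: inference ----------------------------------------------
    cov = metric_table[["age", "sex", "education_years", "mean_fd"]].to_numpy(float)
    group = metric_table["group"].to_numpy()
    stat_results = {}
    for resp in ("loading", "entropy"):
        fit = stats.ancova_f(metric_table[resp].to_numpy(float), group, cov)
        post = stats.posthoc_pairwise(fit, config.posthoc)
        d = stats.cohens_d_from_f(fit.result.statistic, *fit.result.df)
        stat_results[resp] = {
            "F": fit.result.statistic, "df": list(fit.result.df),
            "p": fit.result.p_value, "cohens_d": d,
            "adjusted_means": fit.adjusted_means,
            "posthoc": post.to_dict(orient="records"),
        }
    patients = metric_table[metric_table.group != "HC"]
    for resp in ("loading", "entropy"):
        reg = stats.regress_symptoms(
            patients["disorganization"].to_numpy(float),
            patients[resp].to_numpy(float),
            patients[["age", "sex", "education_years", "mean_fd"]].to_numpy(float),
        )
        stat_results[f"symptom_on_{resp}"] = {
            "B": reg.statistic, "p": reg.p_value, "ci95": list(reg.ci95),
        }
    if config.voxelwise and nh_z_stack is not None:
        vres = stats.permutation_fwe(
            nh_z_stack, group, cov, dmn_mask, n_perm=config.n_perm,
            seed=config.seed, min_cluster=config.min_cluster, alpha=config.alpha,
        )
        stat_results["voxelwise_nh"] = {
            "n_perm": config.n_perm,
            "surviving_clusters": {str(k): v for k, v in vres.cluster_sizes.items()},
        }
    report["stat_results"] = _jsonable(stat_results)
    _stage(report, "inference", alpha=config.alpha, posthoc=config.posthoc)

    # --- outputs ----------------------------------------------------------
    _write_outputs(out, config, report, metric_table, comps, mask, voxel_size)
    return report


def _write_outputs(out, config, report, metric_table, comps, mask, voxel_size):
    import nibabel as nib

    metric_table.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    maps4d = np.zeros((*mask.shape, comps.order), dtype=np.float32)
    for k in range(comps.order):
        vol = np.zeros(mask.shape, dtype=np.float32)
        vol[mask] = comps.spatial_maps[k]
        maps4d[..., k] = vol
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(maps4d, affine), out / "group_components.nii")
    pd.DataFrame(comps.group_timecourses).to_csv(
        out / "group_timecourses.tsv", sep="\t", index=False, float_format="%.8g"
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
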