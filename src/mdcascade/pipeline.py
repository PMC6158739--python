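"""End-to-end orchestration of the synthetic-cohort MD analysis pipeline.

Stages run in dependency order: simulate -> psmd -> voxelwise -> ordering ->
trajectories -> projection -> wmh.  Each stage writes figure-ready tidy CSVs
(and NIfTI maps where applicable) under the output directory and contributes
a block to a machine-readable JSON manifest; identical config + seed yield a
byte-identical manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from . import io as mio
from .projection import build_projection_zone, gm_volume_in_zone, md_gm_association
from .skeleton import SkeletonVolume, compute_psmd
from .synthetic import CohortConfig, generate_cohort
from .tracts import (
    DEFAULT_EYO_GRID,
    build_tract_rois,
    run_ordering_suite,
)
from .trajectories import (
    adjust_for_icv,
    associate_psmd_biomarkers,
    fit_trajectory,
    predict_curves,
)
from .voxelwise import (
    TFCEParams,
    build_design,
    fit_glm_tmap,
    group_contrast_maps,
    permutation_fwe,
)
from .wmh import compare_interactions, split_md_by_wmh, wmh_frequency

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "psmd", "voxelwise", "ordering", "trajectories", "projection", "wmh")

#: biomarkers regressed against PSMD (CSF core markers + amyloid PET)
ASSOCIATION_BIOMARKERS = (
    "csf_abeta42",
    "csf_ttau",
    "csf_ptau181",
    "csf_strem2",
    "pib_precuneus",
)

#: measures whose pathological direction is a decrease
DECREASING_MEASURES = {"csf_abeta42", "hippocampal_volume"}


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple = ALL_STAGES
    n_perm: int = 500
    alpha_fwe: float = 0.05
    alpha_uncorrected: float = 0.01
    tfce: TFCEParams = field(default_factory=TFCEParams)
    eyo_grid: tuple = DEFAULT_EYO_GRID
    frac_threshold: float = 0.02
    max_order: int = 3
    huber_t: float = 1.345
    seed: int = 0

    def stage_seed(self, idx: int) -> int:
        return (self.seed * 10007 + 31 * idx + 7) % (2**31)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all enabled stages and return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = list(config.stages)
    for stage in enabled:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    need = {
        "psmd": ["simulate"],
        "voxelwise": ["simulate"],
        "ordering": ["simulate", "psmd", "voxelwise"],
        "trajectories": ["simulate", "psmd", "ordering"],
        "projection": ["simulate", "ordering"],
        "wmh": ["simulate", "ordering"],
    }
    for stage in enabled:
        for dep in need.get(stage, []):
            if dep not in enabled:
                raise ValueError(f"stage '{stage}' requires stage '{dep}' to be enabled")

    manifest = {"seed": config.seed, "stages": {}}
    ctx = {}
    for stage in ALL_STAGES:
        if stage not in enabled:
            continue
        logger.info("stage %s: start", stage)
        block = _STAGE_FUNCS[stage](config, ctx, outdir)
        manifest["stages"][stage] = block
        logger.info("stage %s: done", stage)
    mio.write_manifest(outdir / "manifest.json", manifest)
    return manifest


def _stage_simulate(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort_cfg = replace(config.cohort, seed=config.stage_seed(0))
    cohort = generate_cohort(cohort_cfg)
    ctx["cohort"] = cohort
    mio.write_subject_table(outdir / "subjects.csv", cohort.subjects)
    mio.save_mask(outdir / "skeleton_mask.nii.gz", cohort.skeleton_mask)
    mio.save_volume(outdir / "atlas_labels.nii.gz", cohort.atlas.labels)
    cohort.biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    mio.write_streamlines_json(outdir / "streamlines.json", cohort.streamlines)
    sub = cohort.subjects
    return {
        "n_carriers": int(sub["mutation_carrier"].sum()),
        "n_noncarriers": int((~sub["mutation_carrier"]).sum()),
        "n_symptomatic": int(sub["cdr_positive"].sum()),
        "n_skeleton_voxels": int(cohort.skeleton_mask.sum()),
        "n_tracts": len(cohort.atlas.names),
        "eyo_mean_carriers": float(sub.loc[sub["mutation_carrier"], "eyo"].mean()),
    }


def _stage_psmd(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    rows = []
    for i, sid in enumerate(cohort.subjects["subject_id"]):
        vol = SkeletonVolume(cohort.md[i], cohort.skeleton_mask, cohort.affine)
        rows.append({"subject_id": sid, "psmd": compute_psmd(vol).value})
    psmd = pd.DataFrame(rows)
    ctx["psmd"] = psmd
    psmd.to_csv(outdir / "psmd.csv", index=False)
    return {
        "n_subjects": len(psmd),
        "psmd_mean": float(psmd["psmd"].mean()),
        "psmd_sd": float(psmd["psmd"].std(ddof=1)),
    }


def _stage_voxelwise(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    design = build_design(cohort.subjects)
    contrast = design.contrast("eyo_x_mutation")
    Y = cohort.md_matrix()
    mask = cohort.skeleton_mask
    perm = permutation_fwe(
        Y,
        design,
        contrast,
        mask,
        params=config.tfce,
        n_perm=config.n_perm,
        seed=config.stage_seed(2),
    )
    sig_mask = (perm.fwe_p <= config.alpha_fwe) & mask
    # relaxed voxel-based criterion (uncorrected one-sided p) for thin tracts
    stat = fit_glm_tmap(Y, design, contrast, mask)
    p_unc = np.ones(mask.shape)
    p_unc[mask] = t_dist.sf(stat.tmap[mask], stat.dof)
    relaxed_mask = (p_unc < config.alpha_uncorrected) & mask
    groups = group_contrast_maps(Y, cohort.subjects, mask)
    ctx.update(sig_mask=sig_mask, relaxed_mask=relaxed_mask, perm=perm, tmap=stat)
    mio.save_volume(outdir / "interaction_tmap.nii.gz", stat.tmap)
    mio.save_volume(outdir / "interaction_fwe_p.nii.gz", perm.fwe_p)
    mio.save_mask(outdir / "sig_mask.nii.gz", sig_mask)
    mio.save_mask(outdir / "relaxed_mask.nii.gz", relaxed_mask)
    return {
        "n_permutations": perm.n_permutations,
        "n_sig_voxels_fwe": int(sig_mask.sum()),
        "n_sig_voxels_uncorrected": int(relaxed_mask.sum()),
        "peak_t": float(stat.tmap[mask].max()),
        "dof": stat.dof,
        "group_contrast_peak_t": {
            name: float(sm.tmap[mask].max()) for name, sm in groups.items()
        },
    }


def _tract_md_table(cohort, rois) -> pd.DataFrame:
    rows = []
    for roi in rois:
        if not roi.included or not roi.mask.any():
            continue
        vals = cohort.md[:, roi.mask].mean(axis=1)
        for sid, v in zip(cohort.subjects["subject_id"], vals):
            rows.append({"subject_id": sid, "measure": roi.tract_name, "value": float(v)})
    return pd.DataFrame(rows)


def _stage_ordering(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    a_priori = [r.name for r in config.cohort.regions if r.a_priori]
    rois = build_tract_rois(
        cohort.atlas, ctx["sig_mask"], a_priori=a_priori, frac_threshold=config.frac_threshold
    )
    # thin a-priori tracts: fall back to the relaxed voxel-based criterion,
    # then to the full tract mask, so the measure exists
    for roi in rois:
        if roi.tract_name in a_priori and roi.n_sig_voxels == 0:
            tract = cohort.atlas.mask(roi.tract_name)
            relaxed = tract & ctx["relaxed_mask"]
            roi.mask = relaxed if relaxed.any() else tract
            roi.n_sig_voxels = int(roi.mask.sum())
            logger.info("a-priori tract %r using relaxed/full mask", roi.tract_name)
    ctx["rois"] = rois
    tract_md = _tract_md_table(cohort, rois)
    ctx["tract_md"] = tract_md
    measures = pd.concat(
        [tract_md, ctx["psmd"].rename(columns={"psmd": "value"}).assign(measure="psmd")],
        ignore_index=True,
    )[["subject_id", "measure", "value"]]
    table, results = run_ordering_suite(
        measures, cohort.subjects, grid=config.eyo_grid, huber_t=config.huber_t
    )
    ctx["ordering"] = (table, results)
    tract_md.to_csv(outdir / "tract_md.csv", index=False)
    table.to_csv(outdir / "ordering.csv", index=False)
    return {
        "included_tracts": sorted(t for t in table["measure"] if t != "psmd"),
        "excluded_tracts": sorted(
            r.tract_name for r in rois if not (r.included and r.mask.any())
        ),
        "earliest_abnormal": {
            row["measure"]: row["earliest_abnormal"] for _, row in table.iterrows()
        },
        "interaction_b": {row["measure"]: row["interaction_b"] for _, row in table.iterrows()},
        "interaction_se": {row["measure"]: row["interaction_se"] for _, row in table.iterrows()},
        "n_outliers_removed": {
            row["measure"]: int(row["n_outliers_removed"]) for _, row in table.iterrows()
        },
    }


def _stage_trajectories(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    subjects = cohort.subjects
    bio = cohort.biomarkers
    wide = bio.pivot(index="subject_id", columns="measure", values="value").reset_index()
    merged = wide.merge(subjects, on="subject_id")
    carrier = merged["mutation_carrier"].to_numpy(bool)
    merged["hippocampal_volume"] = adjust_for_icv(
        merged["hippocampal_volume"].to_numpy(float),
        merged["icv"].to_numpy(float),
        ~carrier,
    )
    # white-matter measures join the cascade: earliest tract + global PSMD
    wm = ctx["tract_md"]
    tract_for_cascade = "forceps_major"
    if tract_for_cascade not in set(wm["measure"]):
        tract_for_cascade = sorted(set(wm["measure"]))[0]
    wm_wide = wm[wm["measure"] == tract_for_cascade][["subject_id", "value"]].rename(
        columns={"value": tract_for_cascade}
    )
    merged = merged.merge(wm_wide, on="subject_id").merge(ctx["psmd"], on="subject_id")
    cascade_measures = [
        "csf_abeta42",
        "csf_ttau",
        "csf_ptau181",
        "csf_strem2",
        "pib_precuneus",
        "hippocampal_volume",
        tract_for_cascade,
        "psmd",
    ]
    grid = np.asarray(config.eyo_grid, dtype=float)
    eyo_all = merged["eyo"].to_numpy(float)
    grid = grid[(grid >= eyo_all.min()) & (grid <= eyo_all.max())]
    curves = []
    orders = {}
    for measure in cascade_measures:
        model = fit_trajectory(
            merged[measure].to_numpy(float),
            eyo_all,
            merged["mutation_carrier"].to_numpy(float),
            measure=measure,
            max_order=config.max_order,
            huber_t=config.huber_t,
        )
        orders[measure] = model.selected_order
        cur = predict_curves(
            model, grid, standardize=True, flip_sign=measure in DECREASING_MEASURES
        )
        cur["measure"] = measure
        curves.append(cur)
    curves = pd.concat(curves, ignore_index=True)
    assoc = associate_psmd_biomarkers(
        ctx["psmd"],
        bio[bio["measure"].isin(ASSOCIATION_BIOMARKERS)],
        subjects,
        huber_t=config.huber_t,
    )
    curves.to_csv(outdir / "trajectory_curves.csv", index=False)
    assoc.to_csv(outdir / "psmd_biomarker_associations.csv", index=False)
    ctx["trajectories"] = {"orders": orders, "assoc": assoc}
    return {
        "selected_order": orders,
        "cascade_tract": tract_for_cascade,
        "psmd_association_B": {r["measure"]: r["B"] for _, r in assoc.iterrows()},
        "psmd_association_p": {r["measure"]: r["p"] for _, r in assoc.iterrows()},
    }


def _stage_projection(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    tract_md = ctx["tract_md"]
    tracts = sorted(set(tract_md["measure"]))
    zones = {}
    rows = []
    for tract in tracts:
        bundle = cohort.streamlines.get(tract)
        if not bundle:
            continue
        zone = build_projection_zone(bundle, cohort.gm_mask, tract_name=tract)
        if not zone.voxels:
            logger.info("tract %r: empty projection zone", tract)
            continue
        zones[tract] = zone
        for i, sid in enumerate(cohort.subjects["subject_id"]):
            rows.append(
                {
                    "subject_id": sid,
                    "measure": tract,
                    "value": gm_volume_in_zone(cohort.gm_density[i], zone),
                }
            )
    volumes = pd.DataFrame(rows)
    assoc = md_gm_association(tract_md, volumes, cohort.subjects, huber_t=config.huber_t)
    volumes.to_csv(outdir / "projection_volumes.csv", index=False)
    assoc.to_csv(outdir / "md_gm_associations.csv", index=False)
    ctx["projection"] = {"zones": zones, "assoc": assoc}
    return {
        "zone_voxels": {t: len(z.voxels) for t, z in zones.items()},
        "association_B": {r["measure"]: r["B"] for _, r in assoc.iterrows()},
        "association_fdr_p": {r["measure"]: r["fdr_p"] for _, r in assoc.iterrows()},
        "n_tracts_fdr_sig": int((assoc["fdr_p"] < 0.05).sum()),
    }


def _stage_wmh(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    carrier = cohort.subjects["mutation_carrier"].to_numpy(bool)
    freq = {}
    for label, sel in (("carriers", carrier), ("noncarriers", ~carrier)):
        fm = wmh_frequency(list(cohort.wmh[sel]), group=label)
        freq[label] = fm
        mio.save_volume(outdir / f"wmh_frequency_{label}.nii.gz", fm.data)
    # split by lesion status over the full atlas tract mask: at desk scale the
    # significant-voxel ROI is too small to partition into WMH vs normal tissue
    rows_in, rows_out = [], []
    for roi in ctx["rois"]:
        if not (roi.included and roi.mask.any()):
            continue
        tract_mask = cohort.atlas.mask(roi.tract_name)
        for i, sid in enumerate(cohort.subjects["subject_id"]):
            vol = SkeletonVolume(cohort.md[i], cohort.skeleton_mask, cohort.affine)
            mean_in, mean_out = split_md_by_wmh(vol, cohort.wmh[i], tract_mask)
            if mean_in is not None:
                rows_in.append({"subject_id": sid, "measure": roi.tract_name, "value": mean_in})
            if mean_out is not None:
                rows_out.append({"subject_id": sid, "measure": roi.tract_name, "value": mean_out})
    inside = pd.DataFrame(rows_in, columns=["subject_id", "measure", "value"])
    outside = pd.DataFrame(rows_out, columns=["subject_id", "measure", "value"])
    block = {
        "freq_max": {k: float(v.data.max()) for k, v in freq.items()},
        "freq_mean": {k: float(v.data.mean()) for k, v in freq.items()},
    }
    try:
        comp = compare_interactions(inside, outside, cohort.subjects, huber_t=config.huber_t)
        comp.to_csv(outdir / "wmh_interaction_comparison.csv", index=False)
        block["interaction_inside_b"] = {
            r["measure"]: r["inside_b"] for _, r in comp.iterrows()
        }
        block["interaction_outside_b"] = {
            r["measure"]: r["outside_b"] for _, r in comp.iterrows()
        }
        block["n_tracts_compared"] = len(comp)
    except ValueError as exc:
        logger.info("WMH inside/outside comparison unavailable: %s", exc)
        block["n_tracts_compared"] = 0
    return block


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "psmd": _stage_psmd,
    "voxelwise": _stage_voxelwise,
    "ordering": _stage_ordering,
    "trajectories": _stage_trajectories,
    "projection": _stage_projection,
    "wmh": _stage_wmh,
}
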