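"""End-to-end orchestration: simulate (or load) -> preprocess -> FCD ->
group statistics with cluster-extent correction -> regional correlations ->
cohort table.  All outputs (NIfTI maps, CSV/TSV tables, provenance log) are
written under a results directory; re-running with the same configuration
and seed reproduces them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohortstats import build_table1
from .config import PipelineConfig
from .correlate import correlation_report, extract_region_means
from .fcd import FcdGeometry, compute_fcd, normalize_fcd, smooth_fcd_maps
from .groupstats import (
    ClusterTable,
    extract_clusters,
    monte_carlo_extent_threshold,
    one_sample_t,
    one_way_anova,
    posthoc_t,
)
from .images import FcdPipeError, save_map
from .preprocess import run_preprocessing
from .synth import GROUPS, Cohort, simulate_cohort

log = logging.getLogger("fcdpipe")

MAP_TYPES = ("total", "local", "distant")
GROUP_PAIRS = (("control", "nonHE"), ("control", "MHE"), ("MHE", "nonHE"))


def tissue_masks(grid_shape) -> tuple[np.ndarray, np.ndarray]:
    """Arbitrary labelled nuisance regions for synthetic data: two small
    blocks on opposite face centers of the grid (stand-ins for CSF and
    white matter; the default hub layout occupies the corners)."""
    shape = tuple(grid_shape)
    my, mz = shape[1] // 2, shape[2] // 2
    csf = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    csf[0:2, my - 1:my + 1, mz - 1:mz + 1] = True
    wm[shape[0] - 2:shape[0], my - 1:my + 1, mz - 1:mz + 1] = True
    return csf, wm


def preprocess_and_map(config: PipelineConfig, cohort: Cohort, subject_index: int,
                       dtype=np.float64, geometry=None):
    """Run one subject through conditioning and FCD mapping; returns the
    smoothed, normalized FcdMaps."""
    bold = cohort.bold(subject_index)
    motion = cohort.motion[subject_index]
    csf, wm = tissue_masks(bold.shape)
    pp = config.preprocess
    clean = run_preprocessing(
        bold, motion, csf, wm, n_discard=pp.n_discard,
        low_hz=pp.low_hz, high_hz=pp.high_hz, use_global=pp.use_global,
    )
    fc = config.fcd
    maps = compute_fcd(
        clean, r_threshold=fc.r_threshold, local_radius_mm=fc.local_radius_mm,
        distant_radius_mm=fc.distant_radius_mm, block_size=fc.block_size,
        dtype=dtype, geometry=geometry,
    )
    maps = normalize_fcd(maps, per_map=fc.normalize_per_map)
    return smooth_fcd_maps(maps, config.stats.smooth_fwhm_mm)


def group_map_stacks(config: PipelineConfig, cohort: Cohort, dtype=np.float64,
                     geometry=None):
    """FCD map stacks per group for included subjects.

    Returns (stacks, covariates, included_records) where stacks maps group
    name -> {map type -> (n_subjects, x, y, z) array}.
    """
    if geometry is None:
        geometry = FcdGeometry(
            np.ones(tuple(config.synth.grid_shape), bool),
            config.synth.voxel_size_mm, config.fcd.local_radius_mm,
            config.fcd.distant_radius_mm, config.fcd.block_size, dtype,
        )
    stacks: dict[str, dict[str, list]] = {}
    cov_rows = {g: [] for g in GROUPS}
    included = {g: [] for g in GROUPS}
    for i, rec in enumerate(cohort.records):
        if not rec.included:
            log.info("excluding %s (head motion)", rec.subject_id)
            continue
        maps = preprocess_and_map(config, cohort, i, dtype=dtype, geometry=geometry)
        stacks.setdefault(rec.group, {m: [] for m in MAP_TYPES})
        for m in MAP_TYPES:
            stacks[rec.group][m].append(maps.map(m))
        cov_rows[rec.group].append(
            {"age": rec.age_y, "sex": rec.sex, "education": rec.education_y}
        )
        included[rec.group].append(rec)
    out = {
        g: {m: np.stack(v) for m, v in d.items()} for g, d in stacks.items()
    }
    covs = {g: pd.DataFrame(cov_rows[g]) for g in out}
    return out, covs, included


def simulate_null_field_pool(config: PipelineConfig, n_pool: int, seed,
                             dtype=np.float64) -> dict:
    """FCD maps of connectivity-free synthetic subjects, one stack per map
    type: the subject-level null fields for Monte-Carlo cluster correction.

    Each pool member is white-structure BOLD noise (no planted couplings,
    same grid/volumes/motion model as the analysis) pushed through the
    identical conditioning, FCD, normalization and smoothing chain, so the
    null fields carry the exact spatial and distributional signature of
    the analyzed maps.
    """
    from dataclasses import replace as dc_replace

    from .synth import CohortConfig

    null_spec = dc_replace(config.connectivity_spec(),
                           local_coupling=0.0, distant_coupling=0.0)
    cc = CohortConfig(group_sizes={"control": max(int(n_pool), 2)}, spec=null_spec)
    cohort = Cohort(cc, seed)
    geometry = FcdGeometry(
        np.ones(tuple(config.synth.grid_shape), bool), config.synth.voxel_size_mm,
        config.fcd.local_radius_mm, config.fcd.distant_radius_mm,
        config.fcd.block_size, dtype,
    )
    pool = {m: [] for m in MAP_TYPES}
    for i in range(len(cohort)):
        maps = preprocess_and_map(config, cohort, i, dtype=dtype,
                                  geometry=geometry)
        for m in MAP_TYPES:
            pool[m].append(maps.map(m))
    return {m: np.stack(v) for m, v in pool.items()}


def extent_nulls(config: PipelineConfig, group_sizes, seed, dtype=np.float64,
                 field_pool: dict | None = None) -> dict:
    """Per-map-type cluster-extent nulls from a shared null field pool."""
    st = config.stats
    mask = np.ones(tuple(config.synth.grid_shape), dtype=bool)
    if field_pool is None:
        field_pool = simulate_null_field_pool(
            config, max(st.null_pool_size, sum(group_sizes)), seed, dtype=dtype,
        )
    nulls = {}
    for m in MAP_TYPES:
        nulls[m] = monte_carlo_extent_threshold(
            mask, voxel_p=st.voxel_p, smoothness_fwhm_mm=st.smooth_fwhm_mm,
            voxel_size_mm=config.synth.voxel_size_mm,
            connectivity=st.connectivity, alpha=st.alpha,
            n_iterations=st.n_iterations, seed=seed + 1,
            group_sizes=list(group_sizes), n_covariates=3,
            field_pool=field_pool[m],
        )
    return nulls


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    out_dir: Path
    config: PipelineConfig
    extent_thresholds: dict                              # map type -> int
    anova_tables: dict = field(default_factory=dict)     # map type -> ClusterTable
    posthoc_tables: dict = field(default_factory=dict)   # (map, a, b) -> ClusterTable
    correlations: dict = field(default_factory=dict)     # (map, group) -> DataFrame
    table1: pd.DataFrame | None = None


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    cohort: Cohort | None = None,
    save_subject_maps: bool = False,
    dtype=np.float64,
) -> PipelineResult:
    """Execute the full analysis and write all outputs under ``out_dir``."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = simulate_cohort(config.cohort_config(), config.seed)
    cohort.phenotype_frame().to_csv(
        out / "participants.tsv", sep="\t", index=False, float_format="%.4f"
    )
    for i, rec in enumerate(cohort.records):
        cohort.motion[i].to_tsv(out / f"{rec.subject_id}_motion.tsv")

    # cohort table -----------------------------------------------------------
    result = PipelineResult(out_dir=out, config=config, extent_thresholds={})
    result.table1 = build_table1(cohort.records)
    result.table1.to_csv(out / "table1.csv", index=False)
    with open(out / "table1.txt", "w") as fh:
        fh.write(result.table1.drop(columns=["p_raw"]).to_string(index=False) + "\n")

    # per-subject maps -------------------------------------------------------
    stacks, covs, _ = group_map_stacks(config, cohort, dtype=dtype)
    groups = [g for g in GROUPS if g in stacks]
    if len(groups) < 2:
        raise FcdPipeError("need at least 2 groups with included subjects")
    voxel = config.synth.voxel_size_mm
    mask = np.ones(tuple(config.synth.grid_shape), dtype=bool)
    if save_subject_maps:
        for g in groups:
            for m in MAP_TYPES:
                suffix = {"total": "totalFCD", "local": "lFCD", "distant": "dFCD"}[m]
                for s_idx in range(stacks[g][m].shape[0]):
                    save_map(stacks[g][m][s_idx], voxel,
                             out / f"{g}_{s_idx:03d}_{suffix}.nii.gz")

    # cluster-extent nulls (resampled from a pool of null FCD maps) ----------
    st = config.stats
    nulls = extent_nulls(
        config, [stacks[g]["total"].shape[0] for g in groups],
        seed=config.seed + 1, dtype=dtype,
    )
    result.extent_thresholds = {m: nulls[m].extent_threshold for m in MAP_TYPES}
    with open(out / "cluster_null.json", "w") as fh:
        json.dump({
            "voxel_p": st.voxel_p, "alpha": st.alpha,
            "n_iterations": st.n_iterations,
            "smoothness_fwhm_mm": st.smooth_fwhm_mm,
            "connectivity": st.connectivity, "seed": config.seed + 1,
            "null_pool_size": st.null_pool_size,
            "extent_thresholds": result.extent_thresholds,
        }, fh, indent=2)

    # group inference --------------------------------------------------------
    covariates = pd.concat([covs[g] for g in groups], ignore_index=True)
    pheno = cohort.phenotype_frame()
    pheno_included = pheno[[r.included for r in cohort.records]].reset_index(drop=True)
    for m in MAP_TYPES:
        # per-group one-sample t maps (hub pattern within each group)
        for g in groups:
            ost = one_sample_t(stacks[g][m], mask)
            save_map(ost.stat_map, voxel, out / f"onesample_{g}_{m}_t.nii.gz")
        anova = one_way_anova([stacks[g][m] for g in groups], mask,
                              covariates=covariates)
        save_map(anova.stat_map, voxel, out / f"anova_{m}_F.nii.gz")
        clusters = extract_clusters(
            anova, voxel_p=st.voxel_p,
            extent_threshold=result.extent_thresholds[m],
            connectivity=st.connectivity, voxel_size_mm=voxel,
        )
        clusters.table.to_csv(out / f"anova_{m}_clusters.csv", index=False)
        save_map(clusters.label_map, voxel, out / f"anova_{m}_labels.nii.gz")
        result.anova_tables[m] = clusters
        sig = clusters.significant_mask()
        for ga, gb in GROUP_PAIRS:
            if ga not in stacks or gb not in stacks or not sig.any():
                continue
            pair_cov = pd.concat([covs[ga], covs[gb]], ignore_index=True)
            t_res = posthoc_t(stacks[ga][m], stacks[gb][m], sig, covariates=pair_cov)
            ct = extract_clusters(
                t_res, voxel_p=st.voxel_p,
                extent_threshold=result.extent_thresholds[m],
                connectivity=st.connectivity, voxel_size_mm=voxel,
            )
            ct.table.to_csv(out / f"posthoc_{m}_{ga}_vs_{gb}_clusters.csv", index=False)
            result.posthoc_tables[(m, ga, gb)] = ct

        # regional correlations with clinical scores, per patient group ------
        if sig.any() and len(clusters):
            n_regions = len(clusters)
            all_means = extract_region_means(
                [s for g in groups for s in stacks[g][m]], clusters.label_map
            )
            for g in ("nonHE", "MHE"):
                if g not in groups:
                    continue
                rows = pheno_included["group"] == g
                means_g = all_means[rows.to_numpy()].reset_index(drop=True)
                clin = pheno_included[rows].reset_index(drop=True)
                cov_g = covs[g]
                rep = correlation_report(
                    means_g, clin, ["nct_a", "dst", "ammonia"], covariates=cov_g,
                    alpha=config.correlate.alpha, n_regions=n_regions,
                )
                rep.to_csv(out / f"correlations_{m}_{g}.csv", index=False)
                result.correlations[(m, g)] = rep

    # provenance -------------------------------------------------------------
    with open(out / "provenance.json", "w") as fh:
        json.dump({
            "fcdpipe_version": __version__,
            "seed": config.seed,
            "config": config.to_flat_dict(),
            "extent_thresholds": result.extent_thresholds,
            "elapsed_s": round(time.time() - t0, 2),
        }, fh, indent=2, default=str)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return result
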