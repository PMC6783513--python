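"""Canonical synthetic study conditions used throughout the package.

These are the fixed cohort geometries for the package's calibration and
recovery studies; they are deliberately small enough that the full pipeline
runs on one CPU in minutes.

``null_cohort_config``
    Exchangeable two-group cohort (no injected effect), 10+10 subjects,
    24-cube grid — used to verify that the classifier, the permutation test
    and the cluster correction are honest under the null.
``fwe_cohort_config``
    Null cohort with a single compact 10-cube gray-matter region.  The
    family-wise-error calibration of the cluster correction requires the
    null map's spatial covariance to be kernel-induced; one compact region
    satisfies the Gaussian-random-field assumption, whereas many small
    latent-sharing blocks would not (their maps carry block-wise
    equicorrelation at any distance).
``recovery_cohort_config``
    20+20 cohort with a strong injected effect (coupling 0.8) in one of 100
    regions, the effect region occupying ~1% of the gray mask so the top-1%
    discriminative weight map can resolve it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureSpec, FeatureTable, build_feature_table
from .simulate import SimulationConfig, region_masks, simulate_cohort

__all__ = [
    "null_cohort_config",
    "fwe_cohort_config",
    "recovery_cohort_config",
    "fcs_table_for",
    "recovery_metrics",
    "fwe_replicate",
]


def null_cohort_config(seed: int, n_per_group: tuple[int, int] = (10, 10)) -> SimulationConfig:
    return SimulationConfig(
        n_per_group=n_per_group,
        n_regions=6,
        region_shape=(2, 2, 2),
        effect_strength=0.0,
        seed=seed,
    )


def fwe_cohort_config(seed: int, n_per_group: tuple[int, int] = (10, 10)) -> SimulationConfig:
    return SimulationConfig(
        n_per_group=n_per_group,
        regions=[((6, 6, 6), (10, 10, 10))],
        effect_region=0,
        coupled_regions=(),
        effect_strength=0.0,
        seed=seed,
    )


def recovery_cohort_config(seed: int, effect_strength: float = 0.8,
                           n_per_group: tuple[int, int] = (20, 20)) -> SimulationConfig:
    return SimulationConfig(
        n_per_group=n_per_group,
        n_regions=100,
        region_shape=(3, 3, 3),
        effect_strength=effect_strength,
        seed=seed,
    )


def fcs_table_for(
    config: SimulationConfig, spec: FeatureSpec | None = None
) -> tuple[FeatureTable, pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate a cohort in memory and build its FCS feature table.

    Returns (table, manifest, gray_mask, parcellation).
    """
    manifest, series, _ = simulate_cohort(config)
    mask, parc = region_masks(config)
    spec = spec or FeatureSpec(kind="FCS")
    table = build_feature_table(series, manifest, spec, mask=mask)
    return table, manifest, mask, parc


def recovery_metrics(seed: int, effect_strength: float = 0.8,
                     score: str = "PSQI") -> dict[str, float]:
    """One signal-recovery replicate on the strong-effect cohort.

    Runs the full FCS classification, back-projects the averaged SVM weight
    vector, thresholds it to the top 1% by absolute weight, and compares the
    largest positive cluster with the injected effect region (Dice overlap,
    peak containment); also correlates the cluster-mean FCS with the linked
    clinical score over the whole cohort.
    """
    from .groupstats import cluster_score_correlation
    from .maps import extract_clusters, top_percent_threshold, vector_to_map
    from .mvpa import CVConfig, run_cv

    cfg = recovery_cohort_config(seed, effect_strength=effect_strength)
    table, manifest, mask, parc = fcs_table_for(cfg)
    cv = run_cv(table, CVConfig(seed=seed + 1))

    wmap = vector_to_map(cv.weights, table.index_map, table.grid_shape)
    thr = top_percent_threshold(wmap, mask, 1.0)
    positive = [r for r in extract_clusters(thr, min_size=2, affine=cfg.affine)
                if r.sign > 0]
    effect_vox = set(map(tuple, np.argwhere(parc == cfg.effect_region + 1)))
    if positive:
        top = positive[0]
        cl_vox = set(map(tuple, top.voxels))
        dice = 2 * len(effect_vox & cl_vox) / (len(effect_vox) + len(cl_vox))
        peak_inside = float(top.peak_voxel in effect_vox)
        maps = np.stack([vector_to_map(x, table.index_map, table.grid_shape)
                         for x in table.X])
        r, p = cluster_score_correlation(maps, top, manifest[score].to_numpy())
    else:
        dice, peak_inside, r, p = 0.0, 0.0, 0.0, 1.0
    return {
        "accuracy": cv.mean_metrics["accuracy"],
        "auc": cv.mean_metrics["auc"],
        "dice": dice,
        "peak_inside": peak_inside,
        "score_r": r,
        "score_p": p,
    }


def fwe_replicate(seed: int, n_sim: int = 200) -> bool:
    """One family-wise-error replicate: does any cluster survive the
    AlphaSim-corrected group comparison on a null cohort?"""
    from .groupstats import (
        alphasim_threshold,
        apply_cluster_correction,
        estimate_fwhm,
        voxelwise_glm,
    )
    from .maps import vector_to_map

    cfg = fwe_cohort_config(seed)
    table, manifest, mask, _ = fcs_table_for(cfg)
    maps = np.stack([vector_to_map(x, table.index_map, table.grid_shape)
                     for x in table.X])
    glm = voxelwise_glm(maps, mask, table.labels,
                        table.covariates[["age", "sex", "education"]])
    fw = estimate_fwhm(glm.residuals, mask, cfg.voxel_size_mm)
    corr = alphasim_threshold(mask, fw, cfg.voxel_size_mm,
                              voxel_p=0.01, cluster_alpha=0.05,
                              n_sim=n_sim, seed=seed + 10_007)
    recs = apply_cluster_correction(glm, corr, affine=cfg.affine)
    return bool(recs)
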