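"""Mass-univariate group comparison with Monte-Carlo cluster correction.

Voxel-wise two-sample comparison is an OLS fit per voxel of
``map ~ intercept + group + covariates`` with the t statistic of the group
column; residual maps feed a Gaussian-random-field smoothness estimate
(per-axis FWHM from the variance ratio of first spatial differences), which
parameterizes an AlphaSim-style Monte-Carlo simulation of the null maximum
cluster size.  Clusters of the thresholded t map at least as large as the
simulated critical size control family-wise error at the requested alpha.
Edgewise (large-scale FC) tests use Benjamini-Hochberg FDR instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .maps import ClusterRecord, extract_clusters

__all__ = [
    "GLMResult",
    "SmoothnessEstimate",
    "ClusterCorrection",
    "voxelwise_glm",
    "estimate_fwhm",
    "alphasim_threshold",
    "apply_cluster_correction",
    "fdr_bh",
    "cluster_score_correlation",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class GLMResult:
    t_map: np.ndarray  # 3D, NaN where residual variance is 0
    df: int
    residuals: np.ndarray  # (n_subjects, n_in_mask_voxels)
    mask: np.ndarray
    design_columns: list[str]
    contrast_column: str = "group"


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray  # per-axis (3,)

    def __post_init__(self) -> None:
        self.fwhm_mm = np.asarray(self.fwhm_mm, dtype=np.float64)
        if not np.all(np.isfinite(self.fwhm_mm)) or np.any(self.fwhm_mm <= 0):
            raise ValueError("FWHM estimates must be positive and finite")


@dataclass
class ClusterCorrection:
    voxel_p: float
    cluster_alpha: float
    n_simulations: int
    null_max_sizes: np.ndarray
    min_cluster_size: int


def voxelwise_glm(
    subject_maps: np.ndarray,
    mask: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | None = None,
    patient_label: str = "patient",
) -> GLMResult:
    """Per-voxel OLS of subject maps on [intercept, group, covariates].

    ``subject_maps`` is (n_subjects, nx, ny, nz); the group column is coded
    patient = 1, control = 0, so positive t means patient > control.
    Covariate columns (e.g. age, sex, education) are taken as given; sex may
    be any binary coding.  Voxels with zero residual variance get NaN t.
    """
    mask = np.asarray(mask, dtype=bool)
    groups = np.asarray(groups)
    n = groups.shape[0]
    if subject_maps.shape[0] != n:
        raise ValueError("subject maps and group labels differ in length")
    if min(np.sum(groups == g) for g in np.unique(groups)) < 2:
        raise ValueError("need at least 2 subjects per group")
    cols = [np.ones(n), (groups == patient_label).astype(np.float64)]
    names = ["intercept", "group"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=np.float64))
            names.append(c)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    df = n - x.shape[1]
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")

    y = subject_maps.reshape(n, -1)[:, mask.ravel()]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    g = names.index("group")
    scale = (y**2).mean(axis=0) + 1e-300
    zero_resid = sigma2 <= 1e-20 * scale
    se = np.sqrt(sigma2 * xtx_inv[g, g])
    with np.errstate(invalid="ignore", divide="ignore"):
        t_vals = np.where(~zero_resid, beta[g] / se, np.nan)
    # a vanishing group estimate with vanishing residuals is a genuine zero
    # (e.g. bit-identical maps); only nonzero/zero is left undefined
    t_vals[zero_resid & (np.abs(beta[g]) <= 1e-10 * np.sqrt(scale))] = 0.0
    if np.isnan(t_vals).any():
        warnings.warn(f"{int(np.isnan(t_vals).sum())} voxel(s) with zero residual variance")

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_vals
    return GLMResult(t_map=t_map, df=df, residuals=resid, mask=mask,
                     design_columns=names)


def estimate_fwhm(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float | np.ndarray,
) -> SmoothnessEstimate:
    """Per-axis smoothness (FWHM, mm) of residual fields.

    Classical Gaussian-random-field estimator: for each axis the variance of
    first spatial differences ``s_d^2`` (over in-mask voxel pairs) and the
    point variance ``s^2`` give ``FWHM = d sqrt(-2 ln 2 / ln(1 - s_d^2 /
    (2 s^2)))`` with d the voxel size; estimates are averaged over subjects.
    Ratios >= 2 (rougher than white noise) are flagged and skipped.
    """
    mask = np.asarray(mask, dtype=bool)
    residuals = np.asarray(residuals, dtype=np.float64)
    if residuals.ndim == 2:  # (subjects, in-mask voxels) from the GLM
        vols = np.zeros((residuals.shape[0], *mask.shape))
        vols[:, mask] = residuals
    else:
        vols = residuals
    if vols.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))

    fwhm_subj = []
    for vol in vols:
        vals = vol[mask]
        s2 = vals.var()
        if s2 == 0.0:
            continue
        per_axis = np.full(3, np.nan)
        for ax in range(3):
            pair = mask & np.roll(mask, -1, axis=ax)
            # exclude wrap-around pairs at the far edge
            idx = [slice(None)] * 3
            idx[ax] = slice(-1, None)
            pair[tuple(idx)] = False
            if pair.sum() < 2:
                continue
            diff = np.roll(vol, -1, axis=ax)[pair] - vol[pair]
            sd2 = diff.var()
            ratio = sd2 / (2.0 * s2)
            if not 0.0 < ratio < 1.0:
                continue  # rougher than white noise: no Gaussian width fits
            per_axis[ax] = voxel_size[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(1.0 - ratio))
        fwhm_subj.append(per_axis)
    if not fwhm_subj:
        raise ValueError("smoothness inestimable on every residual map")
    est = np.nanmean(np.array(fwhm_subj), axis=0)
    if np.isnan(est).any():
        raise ValueError(f"smoothness inestimable along axes {np.flatnonzero(np.isnan(est)).tolist()}")
    return SmoothnessEstimate(fwhm_mm=est)


def alphasim_threshold(
    mask: np.ndarray,
    fwhm: SmoothnessEstimate,
    voxel_size_mm: float | np.ndarray,
    voxel_p: float = 0.01,
    cluster_alpha: float = 0.05,
    n_sim: int = 1000,
    connectivity: int = 26,
    seed: int = 0,
) -> ClusterCorrection:
    """Monte-Carlo (AlphaSim-style) critical cluster size.

    Each iteration draws Gaussian white noise on the mask's bounding grid,
    smooths it to the requested per-axis FWHM (periodic boundaries, so the
    smoothed field is stationary), renormalizes to unit variance within the
    mask, applies the two-sided threshold |z| > z_{1-voxel_p/2}, and records
    the largest connected component (positive and negative voxels labeled
    separately, matching the map-side convention).  The critical size is the
    smallest k with empirical P(max cluster >= k) <= cluster_alpha.
    """
    if not 0.0 < voxel_p < 1.0:
        raise ValueError("voxel_p must lie in (0, 1)")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))
    sigma = fwhm.fwhm_mm * FWHM_TO_SIGMA / voxel_size

    # bounding box of the mask, padded by ~2 sigma so smoothing has support
    nz = np.argwhere(mask)
    lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
    pad = np.ceil(2 * sigma).astype(int)
    shape = tuple(int(h - l + 2 * p) for l, h, p in zip(lo, hi, pad))
    sub_mask = np.zeros(shape, dtype=bool)
    inner = tuple(slice(p, p + h - l) for l, h, p in zip(lo, hi, pad))
    sub_mask[inner] = mask[tuple(slice(l, h) for l, h in zip(lo, hi))]

    z_crit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    rng = np.random.default_rng(seed)
    max_sizes = np.empty(n_sim, dtype=np.int64)
    from scipy.ndimage import gaussian_filter

    for i in range(n_sim):
        noise = rng.standard_normal(shape)
        if np.any(sigma > 0):
            noise = gaussian_filter(noise, sigma=sigma, mode="wrap")
        vals = noise[sub_mask]
        z = np.zeros(shape)
        z[sub_mask] = (vals - vals.mean()) / vals.std()
        supra = np.where(np.abs(z) > z_crit, z, 0.0)
        recs = extract_clusters(supra, min_size=1, connectivity=connectivity)
        max_sizes[i] = recs[0].size if recs else 0

    min_size = _critical_size(max_sizes, cluster_alpha)
    return ClusterCorrection(
        voxel_p=voxel_p, cluster_alpha=cluster_alpha, n_simulations=n_sim,
        null_max_sizes=max_sizes, min_cluster_size=min_size,
    )


def _critical_size(max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest k with empirical P(max cluster >= k) <= alpha."""
    n = max_sizes.size
    for k in range(1, int(max_sizes.max()) + 2):
        if np.sum(max_sizes >= k) / n <= alpha:
            return k
    return int(max_sizes.max()) + 1


def apply_cluster_correction(
    glm: GLMResult,
    correction: ClusterCorrection,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> list[ClusterRecord]:
    """Two-sided voxel threshold at |t| > t_{1-voxel_p/2, df}; sign-split
    components of at least the Monte-Carlo critical size survive."""
    if glm.df <= 0:
        raise ValueError("non-positive degrees of freedom")
    t_crit = stats.t.ppf(1.0 - correction.voxel_p / 2.0, glm.df)
    t = np.where(np.isnan(glm.t_map), 0.0, glm.t_map)
    supra = np.where((np.abs(t) > t_crit) & glm.mask, t, 0.0)
    return extract_clusters(supra, min_size=correction.min_cluster_size,
                            connectivity=connectivity, affine=affine)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level q."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def cluster_score_correlation(
    subject_maps: np.ndarray,
    cluster: ClusterRecord,
    scores: np.ndarray,
    subset: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation between per-subject cluster-mean values and a
    clinical score, typically within the patient group (pass ``subset``).

    Returns (r, two-sided p from the t transform of r).
    """
    scores = np.asarray(scores, dtype=np.float64)
    maps = np.asarray(subject_maps, dtype=np.float64)
    if subset is not None:
        subset = np.asarray(subset)
        maps = maps[subset]
        scores = scores[subset]
    if scores.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    means = maps[:, cluster.voxels[:, 0], cluster.voxels[:, 1], cluster.voxels[:, 2]].mean(axis=1)
    if np.ptp(means) == 0.0 or np.ptp(scores) == 0.0:
        raise ValueError("constant cluster means or scores")
    r, p = stats.pearsonr(means, scores)
    return float(r), float(p)
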