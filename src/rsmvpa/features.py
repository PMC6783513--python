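"""Per-subject connectivity features: voxel-wise FCS, large-scale FC, ReHo.

FCS (functional connectivity strength) is a weighted degree centrality: for
each gray-matter voxel, the sum of its Pearson correlations with every other
gray-matter voxel, keeping only correlations above a threshold (default
r > 0.25) so weak and negative correlations are removed.  Large-scale FC is
the Fisher-z-transformed Pearson correlation between atlas-node mean time
series, vectorized over unordered node pairs.  ReHo (regional homogeneity)
is Kendall's coefficient of concordance W between a voxel's time series and
its immediate spatial neighbors (default 26-neighborhood).

All voxel-wise maps are computed inside a gray-matter mask (probability
> 0.2 by default), and smoothed with an isotropic Gaussian kernel (default
6 mm FWHM) at the end of each feature chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import BOLDSeries

__all__ = [
    "FeatureSpec",
    "FeatureTable",
    "make_gm_mask",
    "voxelwise_fcs",
    "zscore_map",
    "fisher_z",
    "gaussian_smooth",
    "kendalls_w",
    "reho_map",
    "node_timeseries",
    "largescale_fc",
    "pair_index_map",
    "build_feature_table",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

#: manifest columns carried into the feature table as covariates
COVARIATE_COLUMNS = ["age", "sex", "education", "ISI", "PSQI", "SAS", "SDS",
                     "duration", "total_sleep_time", "SOL", "WASO",
                     "realized_coupling"]


@dataclass
class FeatureSpec:
    """Configuration of one feature chain.

    kind
        One of ``"FCS"``, ``"largescale_FC"``, ``"ReHo"``.
    fcs_standardize
        How the FCS map is converted to z values: ``"zscore_map"`` (in-mask
        standardization of the summed map; default) or ``"fisher_sum"``
        (arctanh applied to each suprathreshold r before summation).  Both
        readings of the conventional "Fisher z conversion" step are
        available because a sum of correlations exceeds 1 and cannot itself
        be arctanh-transformed.
    """

    kind: str = "FCS"
    r_threshold: float = 0.25
    neighborhood: int = 27
    smooth_fwhm_mm: float = 6.0
    gm_prob_threshold: float = 0.2
    fcs_standardize: str = "zscore_map"

    def __post_init__(self) -> None:
        if self.kind not in ("FCS", "largescale_FC", "ReHo"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.neighborhood not in (7, 19, 27):
            raise ValueError("neighborhood must be one of 7, 19, 27")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.fcs_standardize not in ("zscore_map", "fisher_sum"):
            raise ValueError("fcs_standardize must be 'zscore_map' or 'fisher_sum'")


def make_gm_mask(prob_map: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Boolean mask of voxels with gray-matter probability strictly > threshold."""
    prob_map = np.asarray(prob_map, dtype=np.float64)
    if prob_map.min() < 0.0 or prob_map.max() > 1.0:
        raise ValueError("gray-matter map must contain probabilities in [0, 1]")
    return prob_map > threshold


def _standardized_rows(x: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm, so x @ x.T is the correlation."""
    scale = np.abs(x).max(axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(norms <= 1e-10 * scale)  # constant up to rounding
    if bad.size:
        raise ValueError(f"zero-variance time series at in-mask voxel rows {bad.tolist()}")
    return x / norms[:, None]


def voxelwise_fcs(
    series: BOLDSeries,
    mask: np.ndarray,
    r_threshold: float = 0.25,
    chunk_size: int = 1024,
    fisher_sum: bool = False,
) -> np.ndarray:
    """Voxel-wise functional connectivity strength map.

    For each in-mask voxel i, ``FCS(i) = sum_{j != i} r_ij [r_ij > thr]``
    (strict threshold).  Computed in row chunks so the full voxel-by-voxel
    correlation matrix is never materialized.  With ``fisher_sum`` each
    suprathreshold r is arctanh-transformed before summation.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 in-mask voxels")
    x = _standardized_rows(series.timeseries(mask))
    n = x.shape[0]
    fcs = np.empty(n)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        r = x[start:stop] @ x.T
        r[np.arange(start, stop) - start, np.arange(start, stop)] = 0.0
        keep = r > r_threshold
        vals = fisher_z(r[keep]) if fisher_sum else r[keep]
        contrib = np.zeros_like(r)
        contrib[keep] = vals
        fcs[start:stop] = contrib.sum(axis=1)
    out = np.zeros(mask.shape)
    out[mask] = fcs
    return out


def zscore_map(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize a map to zero mean / unit (population) sd inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    vals = vol[mask]
    sd = vals.std()
    if sd == 0.0:
        raise ValueError("constant map cannot be z-scored")
    out = np.zeros(vol.shape)
    out[mask] = (vals - vals.mean()) / sd
    return out


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform z = arctanh(r).

    |r| >= 1 (possible with duplicated series) is clamped to 1 - 1e-7 with a
    warning rather than returning infinity.
    """
    r_arr = np.asarray(r, dtype=np.float64)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r_arr) >= 1.0):
        warnings.warn("|r| >= 1 clamped before Fisher transform", stacklevel=2)
    out = np.arctanh(np.clip(r_arr, -clip, clip))
    return float(out) if np.isscalar(r) else out


def gaussian_smooth(
    vol: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | np.ndarray,
    mask: np.ndarray | None = None,
    renormalize: bool = True,
) -> np.ndarray:
    """Isotropic Gaussian smoothing with sigma = FWHM / sqrt(8 ln 2).

    Smoothing operates on the zero-filled full grid and is re-masked.  With
    ``renormalize`` (default) the result is divided by the smoothed mask,
    which removes the attenuation a hard mask edge would otherwise cause —
    synthetic masks have a high surface-to-volume ratio.  ``fwhm_mm = 0`` is
    the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    vol = np.asarray(vol, dtype=np.float64)
    if fwhm_mm == 0.0:
        return vol.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size
    if mask is None:
        return ndimage.gaussian_filter(vol, sigma=sigma)
    mask = np.asarray(mask, dtype=bool)
    sm = ndimage.gaussian_filter(np.where(mask, vol, 0.0), sigma=sigma)
    if renormalize:
        wt = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(wt > 0, sm / wt, 0.0)
    out = np.zeros(vol.shape)
    out[mask] = sm[mask]
    return out


def kendalls_w(series_block: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of K series over n timepoints.

    Each series is ranked over time (midranks for ties); with R_t the rank
    sum at timepoint t, ``W = 12 sum_t (R_t - mean R)^2 / (K^2 (n^3 - n))``.
    No tie-correction term is applied.
    """
    block = np.asarray(series_block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] < 2 or block.shape[1] < 2:
        raise ValueError("need K >= 2 series of n >= 2 timepoints")
    k, n = block.shape
    ranks = stats.rankdata(block, axis=1)
    r_t = ranks.sum(axis=0)
    s = ((r_t - r_t.mean()) ** 2).sum()
    return float(12.0 * s / (k**2 * (n**3 - n)))


_NEIGHBOR_OFFSETS = {
    7: lambda d: np.abs(d).sum() <= 1,
    19: lambda d: (d**2).sum() <= 2,
    27: lambda d: np.abs(d).max() <= 1,
}


def _neighborhood_offsets(neighborhood: int) -> np.ndarray:
    rule = _NEIGHBOR_OFFSETS[neighborhood]
    offs = [d for d in np.ndindex(3, 3, 3)]
    offs = [np.array(d) - 1 for d in offs]
    return np.array([d for d in offs if rule(d)])


def reho_map(
    series: BOLDSeries, mask: np.ndarray, neighborhood: int = 27
) -> np.ndarray:
    """Raw ReHo map: Kendall's W of each in-mask voxel with its in-mask
    neighbors (center included in the block; edge voxels use the neighbors
    that exist, so K varies).  Voxels with no in-mask neighbor get 0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    offsets = _neighborhood_offsets(neighborhood)
    coords = np.argwhere(mask)
    ts = series.timeseries(mask)
    n_t = ts.shape[1]
    ranks = stats.rankdata(ts, axis=1)

    index_vol = -np.ones(mask.shape, dtype=np.int64)
    index_vol[mask] = np.arange(coords.shape[0])

    shape = np.array(mask.shape)
    out = np.zeros(mask.shape)
    denom_base = n_t**3 - n_t
    lonely = []
    for row, c in enumerate(coords):
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        rows = index_vol[tuple(pts[ok].T)]
        rows = rows[rows >= 0]
        k = rows.size
        if k < 2:
            lonely.append(tuple(c))
            continue
        r_t = ranks[rows].sum(axis=0)
        s = ((r_t - r_t.mean()) ** 2).sum()
        out[tuple(c)] = 12.0 * s / (k**2 * denom_base)
    if lonely:
        warnings.warn(f"{len(lonely)} voxel(s) had no in-mask neighbors; ReHo set to 0")
    return out


def normalize_reho(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide by the in-mask mean, so the normalized map has in-mask mean 1."""
    mask = np.asarray(mask, dtype=bool)
    mean = vol[mask].mean()
    if mean == 0.0:
        raise ValueError("in-mask mean ReHo is 0; cannot normalize")
    out = np.zeros(vol.shape)
    out[mask] = vol[mask] / mean
    return out


def node_timeseries(
    series: BOLDSeries, atlas: np.ndarray, on_empty: str = "error"
) -> tuple[np.ndarray, np.ndarray]:
    """Node-mean time series for an integer-labeled parcellation.

    Returns ``(node_ts, labels)`` where ``node_ts[i]`` is the mean series of
    voxels labeled ``labels[i]``.  Empty labels raise by default
    (``on_empty="drop"`` drops them instead).
    """
    atlas = np.asarray(atlas)
    if atlas.shape != series.shape:
        raise ValueError("atlas shape does not match volume")
    n = int(atlas.max())
    present = np.unique(atlas[atlas > 0])
    missing = sorted(set(range(1, n + 1)) - set(int(v) for v in present))
    if missing:
        if on_empty == "error":
            raise ValueError(f"empty atlas nodes: {missing}")
        warnings.warn(f"dropping empty atlas nodes: {missing}")
    labels = np.array(sorted(int(v) for v in present))
    node_ts = np.empty((labels.size, series.n_timepoints))
    for i, lab in enumerate(labels):
        node_ts[i] = series.data[atlas == lab].mean(axis=0)
    return node_ts, labels


def pair_index_map(n_nodes: int) -> np.ndarray:
    """(n_pairs, 2) array of unordered node pairs in row-major strict
    upper-triangle order — the packing order of :func:`largescale_fc`."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def largescale_fc(node_ts: np.ndarray) -> np.ndarray:
    """Fisher-z pairwise Pearson correlations of node series.

    Returns a vector of length N(N-1)/2 in row-major strict upper-triangle
    order (pair (i, j), i < j, index per :func:`pair_index_map`).
    """
    node_ts = np.asarray(node_ts, dtype=np.float64)
    if node_ts.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    if np.any(node_ts.std(axis=1) == 0.0):
        bad = np.flatnonzero(node_ts.std(axis=1) == 0.0)
        raise ValueError(f"constant node series at rows {bad.tolist()}")
    r = np.corrcoef(node_ts)
    iu = np.triu_indices(node_ts.shape[0], k=1)
    return np.asarray(fisher_z(r[iu]))


@dataclass
class FeatureTable:
    """Subjects-by-features matrix with labels, covariates and an index map
    from feature column back to voxel coordinate or node pair."""

    X: np.ndarray
    labels: np.ndarray
    covariates: pd.DataFrame
    kind: str
    index_map: np.ndarray  # (n_features, 3) voxel coords or (n_features, 2) node pairs
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None
    subject_ids: np.ndarray | None = None
    spec: FeatureSpec | None = None
    voxel_size_mm: float | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("label count does not match subject rows")
        if self.index_map.shape[0] != self.X.shape[1]:
            raise ValueError("index map does not cover feature columns")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing entries")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            X=self.X[rows],
            labels=self.labels[rows],
            covariates=self.covariates.iloc[rows].reset_index(drop=True),
            kind=self.kind,
            index_map=self.index_map,
            grid_shape=self.grid_shape,
            affine=self.affine,
            mask=self.mask,
            subject_ids=None if self.subject_ids is None else self.subject_ids[rows],
            spec=self.spec,
            voxel_size_mm=self.voxel_size_mm,
        )

    def with_X(self, new_x: np.ndarray) -> "FeatureTable":
        out = FeatureTable(
            X=new_x, labels=self.labels, covariates=self.covariates,
            kind=self.kind, index_map=self.index_map, grid_shape=self.grid_shape,
            affine=self.affine, mask=self.mask, subject_ids=self.subject_ids,
            spec=self.spec, voxel_size_mm=self.voxel_size_mm,
        )
        return out

    def save(self, prefix) -> None:
        """Persist as a two-file pair: ``<prefix>.npy`` (matrix) and
        ``<prefix>.meta.tsv`` (labels, covariates, index map, geometry)."""
        from pathlib import Path

        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.X)
        meta = self.covariates.copy()
        meta.insert(0, "label", self.labels)
        if self.subject_ids is not None:
            meta.insert(0, "id", self.subject_ids)
        idx = pd.DataFrame(self.index_map,
                           columns=[f"index{i}" for i in range(self.index_map.shape[1])])
        header = {
            "kind": self.kind,
            "grid_shape": "" if self.grid_shape is None else "x".join(map(str, self.grid_shape)),
            "affine": "" if self.affine is None else ",".join(f"{v:.17g}" for v in self.affine.ravel()),
            "voxel_size_mm": "" if self.voxel_size_mm is None else f"{self.voxel_size_mm:.17g}",
        }
        with open(prefix.with_suffix(".meta.tsv"), "w") as fh:
            for k, v in header.items():
                fh.write(f"#{k}\t{v}\n")
            fh.write("#subjects\n")
            meta.to_csv(fh, sep="\t", index=False)
            fh.write("#index_map\n")
            idx.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, prefix) -> "FeatureTable":
        from pathlib import Path

        prefix = Path(prefix)
        x = np.load(prefix.with_suffix(".npy"))
        header: dict[str, str] = {}
        lines = prefix.with_suffix(".meta.tsv").read_text().splitlines()
        i = 0
        while lines[i].startswith("#") and lines[i] != "#subjects":
            k, _, v = lines[i][1:].partition("\t")
            header[k] = v
            i += 1
        j = lines.index("#index_map")
        from io import StringIO

        meta = pd.read_csv(StringIO("\n".join(lines[i + 1:j])), sep="\t")
        idx = pd.read_csv(StringIO("\n".join(lines[j + 1:])), sep="\t")
        cov_cols = [c for c in meta.columns if c not in ("id", "label")]
        grid = header.get("grid_shape") or None
        affine = header.get("affine") or None
        return cls(
            X=x,
            labels=meta["label"].to_numpy(),
            covariates=meta[cov_cols],
            kind=header["kind"],
            index_map=idx.to_numpy(),
            grid_shape=None if grid is None else tuple(int(v) for v in grid.split("x")),
            affine=None if affine is None else np.fromstring(affine, sep=",").reshape(4, 4),
            subject_ids=meta["id"].to_numpy() if "id" in meta.columns else None,
            voxel_size_mm=float(header["voxel_size_mm"]) if header.get("voxel_size_mm") else None,
        )


def subject_feature_map(
    series: BOLDSeries, spec: FeatureSpec,
    mask: np.ndarray | None = None, atlas: np.ndarray | None = None,
) -> np.ndarray:
    """One subject's feature representation (3D map, or vector for
    large-scale FC), following the configured chain."""
    vox = float(np.mean(series.voxel_size_mm))
    if spec.kind == "FCS":
        if mask is None:
            raise ValueError("FCS requires a gray-matter mask")
        raw = voxelwise_fcs(series, mask, spec.r_threshold,
                            fisher_sum=(spec.fcs_standardize == "fisher_sum"))
        if spec.fcs_standardize == "zscore_map":
            raw = zscore_map(raw, mask)
        return gaussian_smooth(raw, spec.smooth_fwhm_mm, vox, mask)
    if spec.kind == "ReHo":
        if mask is None:
            raise ValueError("ReHo requires a gray-matter mask")
        raw = reho_map(series, mask, spec.neighborhood)
        raw = normalize_reho(raw, mask)
        return gaussian_smooth(raw, spec.smooth_fwhm_mm, vox, mask)
    node_ts, _ = node_timeseries(series, atlas)
    return largescale_fc(node_ts)


def build_feature_table(
    series_list: list[BOLDSeries],
    manifest: pd.DataFrame,
    spec: FeatureSpec,
    gm_prob: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    atlas: np.ndarray | None = None,
) -> FeatureTable:
    """Assemble the cohort feature table.

    Voxel-wise kinds flatten in-mask voxels in C-order scan of the grid
    (sorted by (x, y, z) index); large-scale FC uses the row-major
    upper-triangle pair order.  Labels and covariates are joined from the
    manifest (rows aligned positionally with ``series_list``).
    """
    if len(series_list) != len(manifest):
        raise ValueError("series list and manifest rows differ")
    if spec.kind in ("FCS", "ReHo"):
        if mask is None:
            if gm_prob is None:
                raise ValueError("need gm_prob or an explicit mask")
            mask = make_gm_mask(gm_prob, spec.gm_prob_threshold)
        index_map = np.argwhere(mask)
    else:
        if atlas is None:
            raise ValueError("large-scale FC requires an atlas")
        index_map = pair_index_map(int(np.asarray(atlas).max()))

    ref_shape = series_list[0].shape
    rows = []
    for s in series_list:
        if s.shape != ref_shape:
            raise ValueError("subject grid mismatch")
        feat = subject_feature_map(s, spec, mask=mask, atlas=atlas)
        rows.append(feat[mask] if spec.kind in ("FCS", "ReHo") else feat)
    x = np.vstack(rows)

    cov_cols = [c for c in COVARIATE_COLUMNS if c in manifest.columns]
    return FeatureTable(
        X=x,
        labels=manifest["group"].to_numpy(),
        covariates=manifest[cov_cols].reset_index(drop=True),
        kind=spec.kind,
        index_map=index_map,
        grid_shape=ref_shape,
        affine=series_list[0].affine,
        mask=None if spec.kind == "largescale_FC" else mask,
        subject_ids=manifest["id"].to_numpy() if "id" in manifest.columns else None,
        spec=spec,
        voxel_size_mm=float(np.mean(series_list[0].voxel_size_mm)),
    )
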