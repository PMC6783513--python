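"""Temporal preprocessing of BOLD series.

The pipeline follows the conventional resting-state order: discard initial
volumes (signal equilibration), voxel-wise linear detrend, ideal band-pass
filter (0.01-0.1 Hz), then nuisance regression of the Friston-24 head-motion
expansion plus CSF, white-matter and global signals.  All operations work on
(n_timepoints, n_voxels) matrices or on :class:`~rsmvpa.volumes.BOLDSeries`;
geometry (shape, affine, TR) is never altered.

Nuisance regressors are themselves band-passed with the same band before
regression (switchable), so the regression cannot reintroduce frequencies
the filter removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import BOLDSeries

__all__ = [
    "NuisanceSet",
    "discard_initial",
    "detrend_linear",
    "bandpass",
    "expand_friston24",
    "regress_nuisance",
    "extract_tissue_signal",
    "preprocess_series",
    "flag_excessive_motion",
]


def flag_excessive_motion(motion6: np.ndarray, max_translation_mm: float = 2.0,
                          max_rotation_deg: float = 2.0) -> bool:
    """Cohort-level exclusion rule: True if any translation exceeds
    ``max_translation_mm`` or any rotation exceeds ``max_rotation_deg``
    (columns 0-2 translations in mm, 3-5 rotations in degrees).  Subjects
    flagged here are dropped from the manifest; no realignment is done."""
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("expected a 6-column motion matrix")
    return bool(
        np.any(np.abs(motion6[:, :3]) > max_translation_mm)
        or np.any(np.abs(motion6[:, 3:]) > max_rotation_deg)
    )


def discard_initial(series: BOLDSeries, n: int) -> BOLDSeries:
    """Drop the first ``n`` volumes (default study protocol discards 10)."""
    if not 0 <= n < series.n_timepoints:
        raise ValueError(
            f"cannot discard {n} of {series.n_timepoints} timepoints"
        )
    return series.with_data(series.data[..., n:])


def _as_time_by_voxel(ts: np.ndarray) -> tuple[np.ndarray, bool]:
    ts = np.asarray(ts, dtype=np.float64)
    squeezed = ts.ndim == 1
    if squeezed:
        ts = ts[:, None]
    return ts, squeezed


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Residuals after least-squares removal of an intercept and linear ramp.

    ``ts`` is (n_timepoints,) or (n_timepoints, n_voxels).
    """
    ts, squeezed = _as_time_by_voxel(ts)
    n = ts.shape[0]
    if n < 3:
        raise ValueError("detrend requires at least 3 timepoints")
    x = np.column_stack([np.ones(n), np.arange(n, dtype=np.float64)])
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)
    res = ts - x @ beta
    return res[:, 0] if squeezed else res


def bandpass(
    ts: np.ndarray, low_hz: float = 0.01, high_hz: float = 0.1, tr_s: float = 2.5
) -> np.ndarray:
    """Ideal (boxcar) frequency-domain band-pass filter.

    DFT bins with frequency strictly outside [low_hz, high_hz] are zeroed;
    the zero-frequency bin is always zeroed, so the output has mean ~0.
    """
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 < low_hz < high_hz <= nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, {nyquist:.4g}] Hz"
        )
    ts, squeezed = _as_time_by_voxel(ts)
    n = ts.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False
    spec = np.fft.rfft(ts, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return out[:, 0] if squeezed else out


def expand_friston24(motion6: np.ndarray) -> np.ndarray:
    """Friston-24 head-motion expansion.

    Columns, in fixed order for the six parameters m1..m6:
    ``[m1..m6, m1(t-1)..m6(t-1), m1^2..m6^2, m1(t-1)^2..m6(t-1)^2]``
    with the lagged columns zero-padded at the first retained volume.
    """
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"expected a 6-column motion matrix, got {motion6.shape}")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    lag = np.zeros_like(motion6)
    lag[1:] = motion6[:-1]
    return np.column_stack([motion6, lag, motion6**2, lag**2])


@dataclass
class NuisanceSet:
    """Nuisance regressor bundle: motion24 + CSF + WM + global columns."""

    motion24: np.ndarray | None = None
    csf: np.ndarray | None = None
    wm: np.ndarray | None = None
    global_signal: np.ndarray | None = None

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        cols, names = [], []
        if self.motion24 is not None:
            m = np.asarray(self.motion24, dtype=np.float64)
            if m.shape[1] != 24:
                raise ValueError("motion24 must have 24 columns")
            cols.append(m)
            names += [f"motion{i + 1}" for i in range(24)]
        for name, col in (("csf", self.csf), ("wm", self.wm),
                          ("global", self.global_signal)):
            if col is not None:
                col = np.asarray(col, dtype=np.float64).reshape(-1, 1)
                cols.append(col)
                names.append(name)
        if not cols:
            raise ValueError("empty nuisance set")
        return np.column_stack(cols), names


def regress_nuisance(ts: np.ndarray, nuisance: NuisanceSet | np.ndarray,
                     names: list[str] | None = None) -> np.ndarray:
    """Per-voxel OLS residuals against the nuisance design (with intercept).

    Constant-zero regressor columns are dropped; a rank-deficient design
    after that cleanup raises, naming the collinear columns.
    """
    if isinstance(nuisance, NuisanceSet):
        design, names = nuisance.matrix()
    else:
        design = np.asarray(nuisance, dtype=np.float64)
        if names is None:
            names = [f"col{i}" for i in range(design.shape[1])]
    ts, squeezed = _as_time_by_voxel(ts)
    n = ts.shape[0]
    if design.shape[0] != n:
        raise ValueError("regressor rows must equal timepoints")

    nonzero = ~np.all(design == 0.0, axis=0)
    design = design[:, nonzero]
    names = [nm for nm, keep in zip(names, nonzero) if keep]
    x = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        collinear = _collinear_columns(x, ["intercept"] + names)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)
    res = ts - x @ beta
    return res[:, 0] if squeezed else res


def _span_basis(design: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Orthonormal basis of the design's column space (drops null directions)."""
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    keep = s > s[0] * 1e-10 if s.size else np.zeros(0, dtype=bool)
    basis = u[:, keep]
    return basis, [f"span{i + 1}" for i in range(basis.shape[1])]


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    bad = []
    for j in range(x.shape[1] - 1, -1, -1):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(x):
            bad.append(names[j])
    return sorted(bad)


def extract_tissue_signal(series: BOLDSeries, mask: np.ndarray) -> np.ndarray:
    """Mean time series over the mask voxels (used for CSF/WM/global)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tissue mask")
    return series.timeseries(mask).mean(axis=0)


def preprocess_series(
    series: BOLDSeries,
    motion6: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    global_mask: np.ndarray | None = None,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    filter_regressors: bool = True,
) -> BOLDSeries:
    """Full temporal chain: discard -> detrend -> band-pass -> nuisance.

    Motion may be supplied per acquired volume (discarded rows are dropped
    to match) or already trimmed.  Tissue/global signals are extracted from
    the filtered data; all regressors are band-passed with the same band by
    default before regression, and the linear ramp is kept in the regression
    design.  With ``filter_regressors`` the whole chain is an orthogonal
    projection (onto in-band directions orthogonal to the filtered
    regressors), so re-applying it to already-processed data is an exact
    no-op and no filtered-out frequency can be reintroduced.
    """
    series = discard_initial(series, n_discard)
    n_t = series.n_timepoints
    shape = series.shape

    flat = series.data.reshape(-1, n_t).T  # time x voxel
    flat = detrend_linear(flat)
    flat = bandpass(flat, low_hz, high_hz, series.tr_s)
    filtered = series.with_data(flat.T.reshape(*shape, n_t))

    cols = NuisanceSet()
    if motion6 is not None:
        motion6 = np.asarray(motion6, dtype=np.float64)
        if motion6.shape[0] == n_t + n_discard:
            motion6 = motion6[n_discard:]
        elif motion6.shape[0] != n_t:
            raise ValueError("motion rows match neither acquired nor retained volumes")
        cols.motion24 = expand_friston24(motion6)
    if csf_mask is not None:
        cols.csf = extract_tissue_signal(filtered, csf_mask)
    if wm_mask is not None:
        cols.wm = extract_tissue_signal(filtered, wm_mask)
    if global_mask is not None:
        cols.global_signal = extract_tissue_signal(filtered, global_mask)

    try:
        design, names = cols.matrix()
    except ValueError:
        design = np.empty((n_t, 0))
        names = []
    ramp = np.arange(n_t, dtype=np.float64)[:, None]
    design = np.column_stack([ramp, design])
    names = ["trend"] + names

    if filter_regressors:
        design = design - design.mean(axis=0)
        design = bandpass(
            np.asarray(design), low_hz, high_hz, series.tr_s
        )
        # filtering can make short designs rank-deficient (the in-band
        # subspace has limited dimension); projecting onto an orthonormal
        # basis of the design span is the identical projection
        design, names = _span_basis(design)
    res = regress_nuisance(filtered.data.reshape(-1, n_t).T, design, names)
    return series.with_data(res.T.reshape(*shape, n_t))
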