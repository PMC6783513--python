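"""Back-projection of feature-space vectors to 3D maps, thresholding, and
connected-component cluster tables with world-coordinate peaks.

A discriminative weight vector (one entry per in-mask voxel, in the C-order
voxel scan used when the feature table was built) is placed back on the
grid, thresholded to its top percentile by absolute value, and decomposed
into connected clusters.  Positive- and negative-valued voxels are labeled
separately by default so a peak's sign is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ClusterRecord",
    "vector_to_map",
    "top_percent_threshold",
    "extract_clusters",
    "peak_to_world",
    "cluster_table",
]


@dataclass
class ClusterRecord:
    """One suprathreshold connected component."""

    voxels: np.ndarray  # (size, 3) 0-based indices
    size: int
    peak_value: float
    peak_voxel: tuple[int, int, int]
    peak_world_mm: tuple[float, float, float]
    sign: int

    def contains(self, voxel: tuple[int, int, int]) -> bool:
        return bool(np.any(np.all(self.voxels == np.asarray(voxel), axis=1)))


def vector_to_map(
    vector: np.ndarray, index_map: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Scatter a feature vector onto the grid (inverse of in-mask flattening);
    out-of-mask voxels are zero."""
    vector = np.asarray(vector, dtype=np.float64)
    index_map = np.asarray(index_map)
    if vector.shape[0] != index_map.shape[0]:
        raise ValueError("vector length does not match index map")
    out = np.zeros(grid_shape)
    out[tuple(index_map.T)] = vector
    return out


def top_percent_threshold(
    vol: np.ndarray, mask: np.ndarray, pct: float = 1.0
) -> np.ndarray:
    """Keep the top ``pct`` percent of in-mask voxels by absolute value.

    ``ceil(pct/100 * n_mask)`` voxels are retained with their signs; ties at
    the cutoff are all retained (the retained count may then exceed the
    ceiling, which is logged).
    """
    if not 0.0 < pct <= 100.0:
        raise ValueError("pct must lie in (0, 100]")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    k = int(np.ceil(pct / 100.0 * n))
    mag = np.abs(vol[mask])
    cutoff = np.sort(mag)[::-1][k - 1]
    keep_in = mag >= cutoff
    if keep_in.sum() > k:
        warnings.warn(
            f"ties at the top-{pct}% cutoff: retaining {int(keep_in.sum())} voxels "
            f"instead of {k}"
        )
    out = np.zeros(vol.shape)
    vals = vol[mask]
    out_vals = np.where(keep_in, vals, 0.0)
    out[mask] = out_vals
    return out


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    vol: np.ndarray,
    min_size: int = 100,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
    split_sign: bool = True,
) -> list[ClusterRecord]:
    """Connected components of the nonzero voxels of a thresholded map.

    With ``split_sign`` (default) positive and negative voxels are labeled
    separately so opposite-signed clusters never merge through adjacency.
    Components smaller than ``min_size`` are dropped; records are sorted by
    size descending.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = _STRUCTURES[connectivity]
    if affine is None:
        affine = np.eye(4)
    vol = np.asarray(vol, dtype=np.float64)

    parts = [vol > 0, vol < 0] if split_sign else [vol != 0]
    records: list[ClusterRecord] = []
    for part in parts:
        labeled, n_comp = ndimage.label(part, structure=structure)
        for comp in range(1, n_comp + 1):
            voxels = np.argwhere(labeled == comp)
            if voxels.shape[0] < min_size:
                continue
            vals = vol[tuple(voxels.T)]
            peak_i = int(np.argmax(np.abs(vals)))
            peak_voxel = tuple(int(v) for v in voxels[peak_i])
            records.append(
                ClusterRecord(
                    voxels=voxels,
                    size=voxels.shape[0],
                    peak_value=float(vals[peak_i]),
                    peak_voxel=peak_voxel,
                    peak_world_mm=peak_to_world(peak_voxel, affine),
                    sign=int(np.sign(vals[peak_i])),
                )
            )
    records.sort(key=lambda r: r.size, reverse=True)
    return records


def peak_to_world(
    voxel: tuple[int, int, int] | np.ndarray, affine: np.ndarray
) -> tuple[float, float, float]:
    """Map a 0-based voxel index to world (MNI) mm via the image affine."""
    affine = np.asarray(affine, dtype=np.float64)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine")
    hom = affine @ np.array([*voxel, 1.0])
    return tuple(float(v) for v in hom[:3])


def cluster_table(records: list[ClusterRecord], value_name: str = "weight") -> pd.DataFrame:
    """Cluster summary table: region label left blank (anatomical naming is
    out of scope), peak mm coordinates, size, peak value."""
    rows = []
    for r in records:
        x, y, z = r.peak_world_mm
        rows.append({
            "region": "",
            "peak_x_mm": x, "peak_y_mm": y, "peak_z_mm": z,
            "cluster_size_voxels": r.size,
            f"peak_{value_name}": r.peak_value,
        })
    return pd.DataFrame(rows)
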