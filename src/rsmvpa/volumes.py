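"""Lightweight containers for 4D BOLD series and 3D label/mask volumes.

Volumes are plain numpy arrays in (x, y, z[, t]) axis order together with a
4x4 affine mapping 0-based voxel indices to world (MNI) millimetre
coordinates, read and written as NIfTI-1 through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["BOLDSeries", "default_affine", "load_bold", "load_volume", "save_volume"]


def default_affine(voxel_size_mm: float, origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Diagonal voxel-to-world affine with isotropic voxel size."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    aff[:3, 3] = origin_mm
    return aff


@dataclass
class BOLDSeries:
    """A 4D voxel-by-time BOLD volume with geometry and repetition time.

    Parameters
    ----------
    data
        Array of shape (nx, ny, nz, n_timepoints), float.
    affine
        4x4 voxel-index -> world-mm transform.
    tr_s
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr_s: float = 2.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def timeseries(self, mask: np.ndarray) -> np.ndarray:
        """In-mask voxel time series as a (n_voxels, n_timepoints) matrix.

        Voxels are ordered by C-order scan of the grid, i.e. sorted by
        (x, y, z) index — the package-wide feature scan order.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("mask shape does not match volume")
        return self.data[mask]

    def with_data(self, data: np.ndarray) -> "BOLDSeries":
        return BOLDSeries(data=data, affine=self.affine.copy(), tr_s=self.tr_s)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_bold(path, tr_s: float | None = None) -> BOLDSeries:
    """Read a 4D NIfTI; TR is taken from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 else 1.0
    return BOLDSeries(data=data, affine=np.asarray(img.affine), tr_s=tr_s)


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI, returning (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def save_volume(data: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))
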