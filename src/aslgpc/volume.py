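"""3-D perfusion volumes and their NIfTI-1 representation.

A :class:`Volume` is the in-memory unit of every image-processing step: a
3-D array of rCBF-like values (scaled CBF units) together with its voxel
spacing and a voxel-to-world affine.  Files on disk are plain NIfTI-1,
read and written through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "ellipsoid_mask", "load_volume", "save_volume"]


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """RAS-oriented affine with the given spacing on the diagonal."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class Volume:
    """A 3-D scalar field with voxel-size metadata.

    Parameters
    ----------
    data
        3-D array of voxel values.
    voxel_size_mm
        Per-axis voxel spacing in millimetres; all entries must be > 0.
    affine
        Voxel-to-world mapping.  Defaults to a diagonal RAS affine built
        from ``voxel_size_mm``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be three positive floats, got {self.voxel_size_mm}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this one's geometry."""
        return Volume(data=np.asarray(data), voxel_size_mm=self.voxel_size_mm, affine=self.affine.copy())


def ellipsoid_mask(grid_shape: tuple[int, int, int], semiaxis_factor: float = 1.05) -> np.ndarray:
    """Boolean brain mask: an inscribed ellipsoid centred on the grid.

    ``semiaxis_factor`` scales the semi-axes relative to the half-extent of
    each axis; the default 1.05 (clipped at the grid boundary) covers about
    60% of the voxels, a deterministic stand-in for a brain mask.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 1 for n in grid_shape):
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    center = [(n - 1) / 2.0 for n in grid_shape]
    semi = [semiaxis_factor * n / 2.0 for n in grid_shape]
    ax = [(np.arange(n) - c) / s for n, c, s in zip(grid_shape, center, semi)]
    r2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    return r2 <= 1.0


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a Volume as float32 NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file into a Volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, voxel_size_mm=zooms, affine=np.asarray(img.affine))
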