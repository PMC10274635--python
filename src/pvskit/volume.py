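"""3D image containers and NIfTI I/O.

A :class:`Volume3D` is a thin carrier for a 3D scalar array plus voxel
dimensions in millimetres.  It is used for raw, denoised and vesselness
images alike; binary PVS masks and integer parcellations ride on the same
grid.  File I/O goes through nibabel so volumes round-trip as standard
NIfTI-1 images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "load_volume", "save_volume", "save_mask", "load_mask"]


@dataclass
class Volume3D:
    """A 3D scalar image with voxel dimensions in mm.

    Parameters
    ----------
    data:
        3D array of intensities (converted to float64).
    voxel_dims:
        Physical voxel edge lengths in mm, one per axis.
    affine:
        Optional 4x4 voxel-to-world matrix.  When absent, a diagonal
        affine built from ``voxel_dims`` is used for file output.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        vd = tuple(float(v) for v in self.voxel_dims)
        if len(vd) != 3 or any(v <= 0 for v in vd):
            raise ValueError(f"voxel_dims must be three positive lengths, got {self.voxel_dims}")
        self.voxel_dims = vd

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume on this grid carrying ``data``."""
        if data.shape != self.data.shape:
            raise ValueError("data shape does not match grid")
        return Volume3D(data, self.voxel_dims, self.affine)

    def _nifti_affine(self) -> np.ndarray:
        if self.affine is not None:
            return np.asarray(self.affine, dtype=float)
        return np.diag([*self.voxel_dims, 1.0])


def load_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI image into a :class:`Volume3D`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, tuple(float(z) for z in zooms), np.asarray(img.affine))


def save_volume(vol: Volume3D, path: str | Path, dtype=np.float32) -> None:
    """Write a :class:`Volume3D` as NIfTI (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(vol.data.astype(dtype), vol._nifti_affine())
    img.header.set_zooms(vol.voxel_dims)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, ref: Volume3D, path: str | Path) -> None:
    """Write a boolean or integer label array on ``ref``'s grid as NIfTI."""
    arr = np.asarray(mask)
    if arr.shape != ref.shape:
        raise ValueError("mask shape does not match reference grid")
    img = nib.Nifti1Image(arr.astype(np.int16), ref._nifti_affine())
    img.header.set_zooms(ref.voxel_dims)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read an integer/boolean NIfTI mask as an int array."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(np.int64)
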