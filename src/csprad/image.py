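"""3D scalar image volumes with anisotropic voxel spacing.

Coordinate convention: arrays are indexed ``(x, y, z)``; a voxel index ``i``
maps to the physical position ``origin + i * spacing`` (voxel centers), with
all quantities in millimetres.  NIfTI affines are restricted to axis-aligned
scaling plus translation; rotated or sheared affines are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge-to-edge physical size along each axis (mm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=np.asarray(data, dtype=np.float64),
                           spacing=self.spacing, origin=self.origin)

    # --- SimpleITK bridge (sitk uses (x,y,z) metadata but z-fastest arrays) ---

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(data=data, spacing=tuple(img.GetSpacing()),
                   origin=tuple(img.GetOrigin()))

    # --- NIfTI I/O ---

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data, affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = np.asarray(img.affine)
        lin = affine[:3, :3]
        off_diagonal = lin - np.diag(np.diag(lin))
        if np.max(np.abs(off_diagonal)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
            raise ValueError(
                f"{path}: affine has rotation/shear terms; only axis-aligned "
                "scaling + translation volumes are supported")
        scales = np.diag(lin)
        if np.any(scales <= 0):
            raise ValueError(f"{path}: affine has non-positive scales {scales}")
        return cls(data=np.asarray(img.dataobj, dtype=np.float64),
                   spacing=tuple(scales), origin=tuple(affine[:3, 3]))


def as_mask(volume: ImageVolume | np.ndarray) -> np.ndarray:
    """Coerce a volume (or array) holding an indicator to a boolean array."""
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    return data > 0.5
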