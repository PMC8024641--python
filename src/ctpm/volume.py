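"""3D image volume container with physical spacing and NIfTI-1 I/O.

The package-wide axis convention is ``(z, y, x)`` = (superior-inferior,
anterior-posterior, left-right), 0-based.  ``spacing_mm`` and ``origin_mm``
follow the same axis order.  Volumes are tagged with an interpolation class so
that resampling operations can pick trilinear vs. nearest-neighbour without
callers having to remember which volume is a label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

CONTINUOUS = "continuous"
LABEL = "label"


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm) and origin.

    Parameters
    ----------
    values
        3D array, axis order (z, y, x).
    spacing_mm
        Voxel edge lengths in mm, one per axis, all strictly positive.
    origin_mm
        Physical coordinate of voxel (0, 0, 0).
    interpolation_class
        ``"continuous"`` (trilinear on resample) or ``"label"``
        (nearest-neighbour; values restricted to integer codes).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interpolation_class: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.interpolation_class not in (CONTINUOUS, LABEL):
            raise ValueError(f"unknown interpolation class {self.interpolation_class!r}")
        if self.interpolation_class == LABEL:
            vals = self.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("label volume contains non-integer codes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same geometry, new voxel data."""
        return replace(self, values=values)

    def copy(self) -> "ImageVolume":
        return replace(self, values=self.values.copy())

    # ---------------------------------------------------------------- I/O
    def affine(self) -> np.ndarray:
        """NIfTI affine mapping array indices (z, y, x) to physical mm."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        dtype = np.int16 if self.interpolation_class == LABEL else np.float32
        img = nib.Nifti1Image(np.asarray(self.values, dtype=dtype), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, interpolation_class: str = CONTINUOUS) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        if interpolation_class == LABEL:
            data = np.round(data).astype(np.int16)
        else:
            data = data.astype(np.float32)
        return cls(data, spacing, origin, interpolation_class)


def as_bool_mask(mask: ImageVolume | np.ndarray) -> np.ndarray:
    """Binary (foreground) view of a mask volume or array."""
    vals = mask.values if isinstance(mask, ImageVolume) else np.asarray(mask)
    return vals > 0
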