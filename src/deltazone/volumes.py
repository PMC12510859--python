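"""In-memory containers for scalar volumes and binary region masks.

A CT scan, a dose grid and an organ mask are all 3-D arrays tied to a
physical grid (per-axis spacing in millimetres plus an origin).  Array axes
are ordered (x, y, z) to match the physical coordinate order used
throughout; voxel (i, j, k) sits at ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "ROIMask", "read_nifti", "write_nifti"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar grid (CT in HU-like units, or dose in Gy)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={arr.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "ImageVolume | ROIMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class ROIMask:
    """A binary mask on an :class:`ImageVolume` grid, optionally labelled
    with the dose zone it represents (e.g. ``"50-55"``)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zone_label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={arr.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "data", arr.astype(bool))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing_mm)) / 1000.0

    def same_grid(self, other: "ImageVolume | ROIMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_nifti(vol: ImageVolume | ROIMask, path: str) -> None:
    """Write a volume or mask as NIfTI; masks are stored as 0/1 uint8."""
    if isinstance(vol, ROIMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
    img = nib.Nifti1Image(data, _affine(vol.spacing_mm, vol.origin_mm))
    nib.save(img, path)


def read_nifti(path: str, as_mask: bool = False) -> ImageVolume | ROIMask:
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asanyarray(img.dataobj)
    if as_mask:
        return ROIMask(data > 0, spacing, origin)
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)
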