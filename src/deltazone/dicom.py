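"""Optional DICOM adapters: CT series, RTDOSE and RTSTRUCT readers.

These map clinical exports onto the package's in-memory containers.  Axes
follow the package convention (x, y, z); only axis-aligned geometry is
supported (no gantry-tilted acquisitions).  Dose grids honor the DICOM
DoseGridScaling factor and are returned in Gy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from skimage.draw import polygon

from .volumes import ImageVolume, ROIMask

__all__ = ["read_ct_series", "read_rtdose", "read_rtstruct_mask"]


def read_ct_series(directory: str | Path) -> ImageVolume:
    """Load an axial CT series (one file per slice) into HU."""
    files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if getattr(ds, "Modality", "") == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found under {directory}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    rows, cols = slices[0].Rows, slices[0].Columns
    data = np.empty((cols, rows, len(slices)), dtype=np.float64)
    for k, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        data[:, :, k] = (ds.pixel_array.astype(np.float64) * slope + inter).T
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(
            slices[0].ImagePositionPatient[2]
        )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    x0, y0, z0 = (float(v) for v in slices[0].ImagePositionPatient)
    return ImageVolume(data, (dx, dy, abs(dz)), (x0, y0, z0))


def read_rtdose(path: str | Path) -> ImageVolume:
    """Load an RTDOSE grid in Gy (DoseGridScaling applied)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError("not an RTDOSE object")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pixel_array is (frame, row, col) = (z, y, x)
    data = ds.pixel_array.astype(np.float64).transpose(2, 1, 0) * scaling
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = abs(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    return ImageVolume(data, (dx, dy, dz), (x0, y0, z0))


def read_rtstruct_mask(
    path: str | Path,
    grid: ImageVolume,
    roi_name: str,
) -> ROIMask:
    """Rasterize one RTSTRUCT contour set onto ``grid``.

    Each planar contour is filled with a polygon scan; slices are matched to
    the nearest grid plane.  Raises KeyError when the ROI name is absent.
    """
    ds = pydicom.dcmread(str(path))
    numbers = {
        r.ROIName: r.ROINumber for r in getattr(ds, "StructureSetROISequence", [])
    }
    if roi_name not in numbers:
        raise KeyError(
            f"ROI {roi_name!r} not in structure set (has: {sorted(numbers)})"
        )
    target = numbers[roi_name]
    mask = np.zeros(grid.shape, dtype=bool)
    sx, sy, sz = grid.spacing_mm
    ox, oy, oz = grid.origin_mm
    for roi in ds.ROIContourSequence:
        if roi.ReferencedROINumber != target:
            continue
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(round((pts[0, 2] - oz) / sz))
            if not 0 <= k < grid.shape[2]:
                continue
            ci = (pts[:, 0] - ox) / sx  # x index
            cj = (pts[:, 1] - oy) / sy  # y index
            ii, jj = polygon(ci, cj, shape=grid.shape[:2])
            mask[ii, jj, k] = True
    return ROIMask(mask, grid.spacing_mm, grid.origin_mm, zone_label=roi_name)
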