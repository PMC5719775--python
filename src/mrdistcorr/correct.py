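"""Rectification of distorted volumes with a distortion map.

The displacement field is defined as delta = MR - CT: a structure truly at
``x`` appears at ``x + delta(x)``.  Correction therefore resamples the
distorted volume at ``x + delta(x)`` for every output voxel ``x`` (inverse
warping with the forward field), using spline intensity interpolation.  No
Jacobian intensity modulation is applied.

Patient volumes are not necessarily centered on the scanner isocenter; the
in-plane offset is recovered from the acquisition header (FOV and position
entries) before map lookups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field import DistortionMap
from .volume import Volume

log = logging.getLogger(__name__)


@dataclass
class HeaderGeometry:
    """Header quantities needed to locate a volume in the isocenter frame."""

    fov_mm: float
    x_dicom_mm: float | None = None
    y_dicom_mm: float | None = None

    def __post_init__(self):
        if self.fov_mm <= 0:
            raise ValueError("FOV must be positive")


def isocenter_shift(header: HeaderGeometry) -> tuple[float, float]:
    """In-plane shift between image center and scanner isocenter:
    ``shift = FOV/2 - position`` per header axis."""
    if header.x_dicom_mm is None or header.y_dicom_mm is None:
        raise ValueError(
            "header position entries missing; pass an explicit --shift override"
        )
    return (
        header.fov_mm / 2.0 - header.x_dicom_mm,
        header.fov_mm / 2.0 - header.y_dicom_mm,
    )


def correct_volume(
    distorted: Volume,
    dmap: DistortionMap,
    shift: tuple[float, float] = (0.0, 0.0),
    interp_order: int = 3,
    chunk_slices: int = 16,
    fill_value: float | None = None,
) -> Volume:
    """Rectify a distorted volume.

    The output voxel at world coordinate ``x`` (isocenter frame, after
    applying the in-plane ``shift``) takes the input intensity interpolated
    at ``x + delta(x)``.  Lookups outside the map's sampled volume follow
    the map's boundary policy (linear extension one pitch, clamp beyond);
    intensity samples outside the input volume are filled with
    ``fill_value`` (default: the volume's minimum).
    """
    data = np.asarray(distorted.data, np.float64)
    if interp_order >= 2:
        coeff = ndimage.spline_filter(data, order=interp_order, mode="nearest")
        prefilter = False
    else:
        coeff = data
        prefilter = True
    if fill_value is None:
        fill_value = float(data.min())
    out = np.empty_like(data)
    nx, ny, nz = distorted.shape
    xs = distorted.axis_coords(0)
    ys = distorted.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    shift3 = np.array([shift[0], shift[1], 0.0])
    origin = np.asarray(distorted.origin_mm)
    voxel = np.asarray(distorted.voxel_mm)
    n_outside = 0
    for k0 in range(0, nz, chunk_slices):
        k1 = min(k0 + chunk_slices, nz)
        zs = distorted.axis_coords(2)[k0:k1]
        pts = np.column_stack(
            [
                np.repeat(gx.ravel()[:, None], len(zs), axis=1).ravel(),
                np.repeat(gy.ravel()[:, None], len(zs), axis=1).ravel(),
                np.tile(zs, nx * ny),
            ]
        )
        delta = dmap.evaluate(pts + shift3)
        sample = pts + delta
        idx = ((sample - origin) / voxel).T
        n_outside += int(
            np.any((idx < 0) | (idx > (np.array([nx, ny, nz]) - 1)[:, None]), axis=0).sum()
        )
        vals = ndimage.map_coordinates(
            coeff, idx, order=interp_order, prefilter=prefilter,
            mode="constant", cval=fill_value,
        )
        out[:, :, k0:k1] = vals.reshape(nx, ny, len(zs))
    if n_outside:
        log.info("correct_volume: %d samples fell outside the input volume", n_outside)
    res = distorted.copy_with(out.astype(np.float32))
    res.meta["corrected"] = True
    return res


def difference_volume(a: Volume, b: Volume) -> Volume:
    """Voxelwise ``a - b`` for QA display; requires identical grids."""
    if a.shape != b.shape or a.voxel_mm != b.voxel_mm or a.origin_mm != b.origin_mm:
        raise ValueError("difference_volume requires identical volume grids")
    return a.copy_with((np.asarray(a.data, np.float64) - b.data).astype(np.float32))
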