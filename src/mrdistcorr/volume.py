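"""3D image volume container with world-coordinate geometry and file I/O.

A :class:`Volume` stores a scalar 3D array indexed ``[ix, iy, iz]`` whose voxel
centers map to world millimetre coordinates via
``world = origin_mm + index * voxel_mm`` (0-based indices, voxel-center
convention).  The world frame is the scanner frame: the isocenter is at the
origin.  Volumes are read and written as NIfTI-1 (via nibabel) or as a flat
DICOM series directory (via pydicom).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

#: axis labels in array order
AXES = ("x", "y", "z")


@dataclass
class Volume:
    """Scalar 3D image with voxel spacing, world origin and modality tag."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = AXES
    modality: str = "MR"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one array axis."""
        n = self.data.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.voxel_mm[axis]

    def world_bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] voxel-center world coordinates."""
        lo = np.array(self.origin_mm)
        hi = lo + (np.array(self.shape) - 1) * np.array(self.voxel_mm)
        return np.stack([lo, hi])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(idx, float) * np.asarray(self.voxel_mm)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, float) - np.asarray(self.origin_mm)) / np.asarray(self.voxel_mm)

    def copy_with(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data, meta=dict(self.meta))

    # -- I/O --------------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(np.asarray(self.data, np.float32), affine)
        img.header.set_xyzt_units("mm")
        img.header["descrip"] = np.bytes_(f"modality={self.modality}"[:79])
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, modality: str | None = None) -> "Volume":
        import nibabel as nib

        img = nib.load(path)
        affine = img.affine
        rot = affine[:3, :3]
        off = np.abs(rot - np.diag(np.diag(rot))).max()
        if off > 1e-3:
            raise ValueError(
                "unsupported NIfTI orientation: affine rotation part is not "
                "diagonal (field: affine)"
            )
        voxel = np.diag(rot)
        if np.any(voxel <= 0):
            raise ValueError("unsupported NIfTI orientation: negative spacing (field: affine)")
        if modality is None:
            descrip = str(np.asarray(img.header["descrip"]).astype(str))
            modality = "CT" if "modality=CT" in descrip else "MR"
        return cls(
            data=np.asarray(img.get_fdata(), np.float32),
            voxel_mm=tuple(voxel),
            origin_mm=tuple(affine[:3, 3]),
            modality=modality,
        )

    def to_dicom_series(self, directory: str, fov_mm: float | None = None) -> None:
        """Write an axial DICOM series, one file per z slice.

        ``ImagePositionPatient``/``PixelSpacing`` carry the world geometry;
        the in-plane FOV (rows x spacing) is what header-based isocenter
        shifts are computed from.
        """
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        os.makedirs(directory, exist_ok=True)
        data = np.asarray(self.data, np.float64)
        lo, hi = data.min(), data.max()
        scale = 4000.0 / (hi - lo) if hi > lo else 1.0
        series_uid = generate_uid()
        study_uid = generate_uid()
        for k in range(self.shape[2]):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.Modality = self.modality
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = study_uid
            ds.SeriesDescription = self.meta.get("description", "mrdistcorr volume")
            ds.InstanceNumber = k + 1
            # pixel array rows = y, columns = x
            sl = np.round((data[:, :, k].T - lo) * scale).astype(np.uint16)
            ds.Rows, ds.Columns = sl.shape
            ds.PixelSpacing = [self.voxel_mm[1], self.voxel_mm[0]]
            ds.SliceThickness = self.voxel_mm[2]
            ds.ImagePositionPatient = [
                self.origin_mm[0],
                self.origin_mm[1],
                self.origin_mm[2] + k * self.voxel_mm[2],
            ]
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.RescaleSlope = 1.0 / scale
            ds.RescaleIntercept = lo
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.PixelData = sl.tobytes()
            pydicom.dcmwrite(os.path.join(directory, f"slice{k:04d}.dcm"), ds)

    @classmethod
    def from_dicom_series(cls, directory: str) -> "Volume":
        import pydicom

        files = sorted(
            os.path.join(directory, f) for f in os.listdir(directory) if f.endswith(".dcm")
        )
        if not files:
            raise ValueError(f"no DICOM files in {directory}")
        dsets = [pydicom.dcmread(f) for f in files]
        dsets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        spacings = {(float(d.PixelSpacing[0]), float(d.PixelSpacing[1])) for d in dsets}
        if len(spacings) > 1:
            raise ValueError("inconsistent DICOM series (field: PixelSpacing)")
        zs = np.array([float(d.ImagePositionPatient[2]) for d in dsets])
        dz = np.diff(zs)
        if len(dz) and (dz.max() - dz.min()) > 1e-3:
            raise ValueError("inconsistent DICOM series (field: ImagePositionPatient z step)")
        d0 = dsets[0]
        slope = float(getattr(d0, "RescaleSlope", 1.0))
        inter = float(getattr(d0, "RescaleIntercept", 0.0))
        slices = [d.pixel_array.astype(np.float32) * slope + inter for d in dsets]
        data = np.stack([s.T for s in slices], axis=2)
        voxel = (
            float(d0.PixelSpacing[1]),
            float(d0.PixelSpacing[0]),
            float(dz[0]) if len(dz) else float(getattr(d0, "SliceThickness", 1.0)),
        )
        vol = cls(
            data=data,
            voxel_mm=voxel,
            origin_mm=(
                float(d0.ImagePositionPatient[0]),
                float(d0.ImagePositionPatient[1]),
                float(zs[0]),
            ),
            modality=str(getattr(d0, "Modality", "MR")),
        )
        vol.meta["fov_mm"] = (
            d0.Columns * float(d0.PixelSpacing[1]),
            d0.Rows * float(d0.PixelSpacing[0]),
        )
        return vol


def read_volume(path: str, modality: str | None = None) -> Volume:
    """Read a NIfTI file or a DICOM series directory."""
    if os.path.isdir(path):
        return Volume.from_dicom_series(path)
    return Volume.from_nifti(path, modality=modality)


def write_volume(volume: Volume, path: str) -> None:
    """Write NIfTI (``.nii``/``.nii.gz`` path) or a DICOM series (directory)."""
    if path.endswith(".nii") or path.endswith(".nii.gz"):
        volume.to_nifti(path)
    else:
        volume.to_dicom_series(path)
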