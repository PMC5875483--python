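"""Read and write CT volumes as DICOM series; coronal reconstruction.

Writing produces minimal but valid CT Image Storage objects, one file per
slice, head-first supine: the volume's longitudinal axis is written as the
patient superior-inferior axis, so the coronal reconstruction used for angle
measurement is the (image-horizontal, longitudinal) plane.  UIDs are derived
deterministically from the volume content and seed so a re-run with the same
inputs reproduces identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .volume import CTVolume

__all__ = [
    "DicomSeriesError",
    "read_dicom_series",
    "write_dicom_series",
    "CoronalProjection",
    "coronal_projection",
]

_SPACING_TOL = 0.01  # fractional tolerance on slice-spacing uniformity
_FIXED_DATE = "20200101"  # fixed synthetic date keeps output deterministic


class DicomSeriesError(IOError):
    """Malformed, mixed, or geometrically inconsistent DICOM series."""


def write_dicom_series(volume: CTVolume, directory: str | Path) -> list[Path]:
    """Write one CT Image Storage file per slice; returns the file list.

    HU values are rounded to the nearest integer and stored as signed 16-bit
    with identity rescale, so a read-back recovers the voxel grid to within
    HU quantization and the geometry exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = volume.shape
    dx, dy, dz = volume.spacing
    x0, y0, z0 = volume.origin

    entropy = [
        "crossjig",
        str(volume.shape),
        str(volume.spacing),
        str(volume.meta.get("seed", 0)),
        str(float(np.sum(volume.voxels[:: max(nx // 8, 1), :: max(ny // 8, 1), :]))),
    ]
    series_uid = generate_uid(entropy_srcs=entropy)
    study_uid = generate_uid(entropy_srcs=entropy + ["study"])
    frame_uid = generate_uid(entropy_srcs=entropy + ["frame"])

    paths = []
    for k in range(nz):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid(entropy_srcs=entropy + [f"slice{k}"])
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "QA^CrossJig"
        ds.PatientID = "CROSSJIG"
        ds.PatientPosition = "HFS"
        ds.StudyDate = ds.SeriesDate = ds.ContentDate = _FIXED_DATE
        ds.StudyTime = ds.SeriesTime = ds.ContentTime = "000000"
        ds.StudyID = "1"
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.AccessionNumber = ""
        ds.ReferringPhysicianName = ""

        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [x0, y0, z0 + k * dz]
        ds.SliceLocation = z0 + k * dz
        ds.PixelSpacing = [dy, dx]  # [row spacing, column spacing]
        ds.SliceThickness = dz
        ds.KVP = 100.0

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = ny
        ds.Columns = nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.RescaleType = "HU"

        pixels = np.rint(volume.voxels[:, :, k]).astype(np.int16).T  # [row=y, col=x]
        ds.PixelData = np.ascontiguousarray(pixels).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Load the single CT series in a directory into a :class:`CTVolume`.

    Slices are ordered by position along the slice normal (filenames are
    ignored); HU are recovered through rescale slope/intercept.  Raises
    :class:`DicomSeriesError` for mixed series, non-uniform slice spacing
    (beyond 1% of nominal), or missing geometry attributes.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise DicomSeriesError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]

    series_uids = {ds.SeriesInstanceUID for ds in slices}
    if len(series_uids) != 1:
        raise DicomSeriesError(f"directory contains {len(series_uids)} series")
    for attr in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        if any(not hasattr(ds, attr) for ds in slices):
            raise DicomSeriesError(f"missing geometry attribute {attr}")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    if any(
        not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop, atol=1e-6)
        for ds in slices
    ):
        raise DicomSeriesError("orientation varies across slices")
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise DicomSeriesError("only axis-aligned (HFS axial) orientations are supported")

    normal = np.cross(iop[:3], iop[3:])
    keyed = sorted(
        slices, key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
    )
    positions = np.array(
        [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in keyed]
    )
    if len(keyed) > 1:
        deltas = np.diff(positions)
        dz = float(np.median(deltas))
        if dz <= 0 or np.any(np.abs(deltas - dz) > _SPACING_TOL * dz):
            raise DicomSeriesError("non-uniform slice spacing beyond tolerance")
    else:
        dz = float(getattr(keyed[0], "SliceThickness", 1.0))

    ref = keyed[0]
    spacing_row, spacing_col = (float(v) for v in ref.PixelSpacing)
    if any(tuple(float(v) for v in ds.PixelSpacing) != (spacing_row, spacing_col) for ds in keyed):
        raise DicomSeriesError("in-plane pixel spacing varies across slices")

    nx, ny = int(ref.Columns), int(ref.Rows)
    vol = np.empty((nx, ny, len(keyed)), dtype=np.float32)
    for k, ds in enumerate(keyed):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[:, :, k] = (ds.pixel_array.astype(np.float32) * slope + intercept).T

    origin = tuple(float(v) for v in ref.ImagePositionPatient)
    meta = {"series_uid": ref.SeriesInstanceUID, "n_files": len(keyed)}
    return CTVolume(vol, spacing=(spacing_col, spacing_row, dz), origin=origin, meta=meta)


@dataclass
class CoronalProjection:
    """Maximum-intensity coronal projection with its display axes.

    ``image[k, i]`` covers horizontal position ``x_mm[i]`` and longitudinal
    slice ``k``; the vertical display coordinate is ``u_mm = -z`` (first
    slice at the top), which makes clockwise-positive apparent angles on the
    displayed image match the sign convention of the angular model.
    """

    image: np.ndarray
    x_mm: np.ndarray
    u_mm: np.ndarray

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(left, right, bottom, top) for matplotlib ``imshow``."""
        return (
            float(self.x_mm[0]),
            float(self.x_mm[-1]),
            float(self.u_mm[-1]),
            float(self.u_mm[0]),
        )


def coronal_projection(volume: CTVolume) -> CoronalProjection:
    """Maximum-intensity projection over the vertical axis."""
    image = volume.voxels.max(axis=1).T  # (nz, nx)
    return CoronalProjection(image=image, x_mm=volume.x_coords, u_mm=-volume.z_coords)
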