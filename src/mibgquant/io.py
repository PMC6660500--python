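"""File formats: DICOM, plain array containers, ROI JSON, cohort CSV.

Planar images and short-axis volumes round-trip through DICOM
secondary-capture objects (single- and multi-frame) and through a plain
array container (``.npy`` data plus a ``.json`` sidecar) that is convenient
in tests. All pixel coordinates are 0-based, row-major.

DICOM UIDs are derived from a hash of the pixel data so that writing the
same image twice produces identical files (reproducibility contract).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import (
    ExplicitVRLittleEndian,
    MultiFrameGrayscaleWordSecondaryCaptureImageStorage,
    SecondaryCaptureImageStorage,
    generate_uid,
)

from .planar import PlanarImage, PolygonRoi, RoiSet, SquareRoi
from .spect import LVGeometry, ShortAxisVolume

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "DEFAULT_PIXEL_SIZE_MM",
    "write_planar_dicom",
    "read_planar_dicom",
    "write_volume_dicom",
    "read_volume_dicom",
    "save_planar_array",
    "load_planar_array",
    "save_volume_array",
    "load_volume_array",
    "save_roi_set",
    "load_roi_set",
    "write_cohort",
    "read_cohort",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


#: Fallback pixel pitch (mm) when a file lacks PixelSpacing.
DEFAULT_PIXEL_SIZE_MM = 4.42


def _deterministic_uid(payload: bytes, salt: str) -> str:
    digest = hashlib.sha256(salt.encode() + payload).hexdigest()
    return generate_uid(entropy_srcs=[digest])


def _base_sc_dataset(sop_class_uid, payload: bytes) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = _deterministic_uid(payload, "instance")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = _deterministic_uid(payload, "study")
    ds.SeriesInstanceUID = _deterministic_uid(payload, "series")
    ds.Modality = "NM"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    return ds


def _counts_to_uint16(counts: np.ndarray) -> np.ndarray:
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("counts exceed the 16-bit DICOM pixel range")
    return np.ascontiguousarray(counts.astype(np.uint16))


def write_planar_dicom(image: PlanarImage, path: Union[str, Path]) -> Path:
    """Write a planar count image as a DICOM secondary-capture object."""
    pixels = _counts_to_uint16(image.counts)
    ds = _base_sc_dataset(SecondaryCaptureImageStorage, pixels.tobytes())
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [f"{image.pixel_size_mm:g}", f"{image.pixel_size_mm:g}"]
    ds.SeriesDescription = f"mIBG planar {image.timepoint}"
    ds.ImageComments = json.dumps(
        {"timepoint": image.timepoint, "duration_min": image.duration_min}
    )
    ds.PixelData = pixels.tobytes()
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_planar_dicom(path: Union[str, Path], timepoint: Optional[str] = None) -> PlanarImage:
    """Read a planar count image from DICOM.

    The time point comes from the embedded metadata unless overridden by the
    ``timepoint`` flag; a missing PixelSpacing falls back to
    :data:`DEFAULT_PIXEL_SIZE_MM` with a logged warning.
    """
    try:
        ds = pydicom.dcmread(path)
        counts = ds.pixel_array
    except (InvalidDicomError, EOFError, ValueError, AttributeError, KeyError) as err:
        raise FormatError(f"cannot read planar DICOM {path}: {err}") from err
    if counts.ndim != 2:
        raise FormatError(f"expected a single-frame planar image in {path}")

    if "PixelSpacing" in ds:
        pixel_size = float(ds.PixelSpacing[0])
    else:
        logger.warning(
            "no PixelSpacing in %s; assuming %.2f mm", path, DEFAULT_PIXEL_SIZE_MM
        )
        pixel_size = DEFAULT_PIXEL_SIZE_MM

    meta = {}
    if getattr(ds, "ImageComments", None):
        try:
            meta = json.loads(ds.ImageComments)
        except json.JSONDecodeError:
            meta = {}
    tp = timepoint or meta.get("timepoint", "early")
    return PlanarImage(
        counts=counts.astype(np.int64),
        pixel_size_mm=pixel_size,
        timepoint=tp,
        duration_min=float(meta.get("duration_min", 10.0)),
    )


def _geometry_to_dict(geometry: LVGeometry) -> dict:
    return {
        "centers": geometry.centers.tolist(),
        "apex_slice": int(geometry.apex_slice),
        "base_slice": int(geometry.base_slice),
        "inner_radius": float(geometry.inner_radius),
        "outer_radius": float(geometry.outer_radius),
    }


def _geometry_from_dict(d: dict) -> LVGeometry:
    return LVGeometry(
        centers=np.asarray(d["centers"], dtype=float),
        apex_slice=int(d["apex_slice"]),
        base_slice=int(d["base_slice"]),
        inner_radius=float(d["inner_radius"]),
        outer_radius=float(d["outer_radius"]),
    )


def write_volume_dicom(volume: ShortAxisVolume, path: Union[str, Path]) -> Path:
    """Write a short-axis volume as a multi-frame DICOM secondary capture;
    the LV-axis geometry travels in the ImageComments JSON."""
    pixels = _counts_to_uint16(volume.counts)
    ds = _base_sc_dataset(
        MultiFrameGrayscaleWordSecondaryCaptureImageStorage, pixels.tobytes()
    )
    ds.NumberOfFrames, ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [f"{volume.voxel_size_mm:g}", f"{volume.voxel_size_mm:g}"]
    ds.SliceThickness = f"{volume.voxel_size_mm:g}"
    ds.SeriesDescription = "mIBG SPECT short-axis"
    ds.ImageComments = json.dumps({"geometry": _geometry_to_dict(volume.geometry)})
    ds.PixelData = pixels.tobytes()
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_volume_dicom(path: Union[str, Path]) -> ShortAxisVolume:
    try:
        ds = pydicom.dcmread(path)
        counts = ds.pixel_array
    except (InvalidDicomError, EOFError, ValueError, AttributeError, KeyError) as err:
        raise FormatError(f"cannot read volume DICOM {path}: {err}") from err
    if counts.ndim != 3:
        raise FormatError(f"expected a multi-frame volume in {path}")
    try:
        meta = json.loads(ds.ImageComments)
        geometry = _geometry_from_dict(meta["geometry"])
    except (AttributeError, KeyError, json.JSONDecodeError) as err:
        raise FormatError(f"volume DICOM {path} lacks LV geometry metadata") from err
    voxel = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else DEFAULT_PIXEL_SIZE_MM
    return ShortAxisVolume(
        counts=counts.astype(np.int64), geometry=geometry, voxel_size_mm=voxel
    )


# ---------------------------------------------------------------------------
# plain array container (.npy + .json sidecar)
# ---------------------------------------------------------------------------

def save_planar_array(image: PlanarImage, base: Union[str, Path]) -> Path:
    base = Path(base)
    np.save(base.with_suffix(".npy"), image.counts)
    sidecar = {
        "kind": "planar",
        "pixel_size_mm": image.pixel_size_mm,
        "timepoint": image.timepoint,
        "duration_min": image.duration_min,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return base


def load_planar_array(base: Union[str, Path]) -> PlanarImage:
    base = Path(base)
    try:
        counts = np.load(base.with_suffix(".npy"))
        sidecar = json.loads(base.with_suffix(".json").read_text())
    except (OSError, ValueError, json.JSONDecodeError) as err:
        raise FormatError(f"cannot read planar array container {base}: {err}") from err
    if sidecar.get("kind") != "planar":
        raise FormatError(f"{base} is not a planar container")
    return PlanarImage(
        counts=counts.astype(np.int64),
        pixel_size_mm=float(sidecar["pixel_size_mm"]),
        timepoint=sidecar["timepoint"],
        duration_min=float(sidecar["duration_min"]),
    )


def save_volume_array(volume: ShortAxisVolume, base: Union[str, Path]) -> Path:
    base = Path(base)
    np.save(base.with_suffix(".npy"), volume.counts)
    sidecar = {
        "kind": "volume",
        "voxel_size_mm": volume.voxel_size_mm,
        "geometry": _geometry_to_dict(volume.geometry),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return base


def load_volume_array(base: Union[str, Path]) -> ShortAxisVolume:
    base = Path(base)
    try:
        counts = np.load(base.with_suffix(".npy"))
        sidecar = json.loads(base.with_suffix(".json").read_text())
    except (OSError, ValueError, json.JSONDecodeError) as err:
        raise FormatError(f"cannot read volume array container {base}: {err}") from err
    if sidecar.get("kind") != "volume":
        raise FormatError(f"{base} is not a volume container")
    return ShortAxisVolume(
        counts=counts.astype(np.int64),
        geometry=_geometry_from_dict(sidecar["geometry"]),
        voxel_size_mm=float(sidecar["voxel_size_mm"]),
    )


# ---------------------------------------------------------------------------
# ROI JSON (vertex lists, 0-based pixel coordinates, row-major)
# ---------------------------------------------------------------------------

def save_roi_set(rois: RoiSet, path: Union[str, Path]) -> Path:
    path = Path(path)
    payload = {
        "heart": {"vertices": rois.heart.vertices.tolist()},
        "mediastinum": {
            "row": rois.mediastinum.row,
            "col": rois.mediastinum.col,
            "size": rois.mediastinum.size,
        },
        "coordinates": "0-based (row, col)",
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_roi_set(path: Union[str, Path]) -> RoiSet:
    try:
        payload = json.loads(Path(path).read_text())
        heart = PolygonRoi(np.asarray(payload["heart"]["vertices"], dtype=float))
        med = payload["mediastinum"]
        square = SquareRoi(row=int(med["row"]), col=int(med["col"]), size=int(med["size"]))
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as err:
        raise FormatError(f"cannot read ROI set {path}: {err}") from err
    return RoiSet(heart=heart, mediastinum=square)


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: pd.DataFrame, path: Union[str, Path], header_comment: Optional[str] = None
) -> Path:
    """Write a cohort table as UTF-8 comma-separated CSV (missing values as
    empty fields); an optional ``#``-prefixed provenance line goes first."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cohort.to_csv(fh, index=False)
    return path


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise FormatError(f"cannot read cohort CSV {path}: {err}") from err
    for col in df.columns:
        if col.startswith(("med_",)) or col in (
            "sex_male", "ischemic", "lbbb", "diabetes", "hypertension",
            "smoker", "dyslipidemia",
        ):
            df[col] = df[col].astype(bool)
    return df
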