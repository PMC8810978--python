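"""Readers and writers for cohort tables and planar images.

Cohort CSV contract: columns ``patient_id, visual_grade, hcl, diagnosis``
(header required; diagnosis spelled ``TTR-CA``, ``LC-CA`` or ``none``; an
empty ``hcl`` cell means unset).  Phantom images are written as 16-bit
PNG with a JSON sidecar recording the generator parameters, and
optionally as a nuclear-medicine-style DICOM secondary capture.  A reader
for planar NM DICOM extracts the count grid, pixel spacing and
post-injection time when present.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .quant import PlanarImage, QuantError
from .reference import Diagnosis
from .synthetic import PatientRecord, PhantomParams

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_phantom_png",
    "read_phantom_png",
    "write_planar_dicom",
    "read_planar_dicom",
    "read_planar_image",
]

COHORT_COLUMNS = ["patient_id", "visual_grade", "hcl", "diagnosis"]


def write_cohort_csv(
    records: list[PatientRecord],
    path: str | Path,
    extra_columns: dict[str, list] | None = None,
) -> None:
    """Write a cohort table, optionally with appended per-record columns."""
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "visual_grade": [r.visual_grade for r in records],
            "hcl": [r.hcl for r in records],
            "diagnosis": [r.diagnosis.value for r in records],
        }
    )
    for name, values in (extra_columns or {}).items():
        if len(values) != len(records):
            raise QuantError(f"extra column {name!r} does not align with records")
        frame[name] = values
    frame.to_csv(path, index=False, float_format="%.6f")


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; malformed rows are reported by number."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise QuantError(f"cohort CSV missing column(s) {missing}")
    records = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            hcl = None if pd.isna(row["hcl"]) else float(row["hcl"])
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    visual_grade=int(row["visual_grade"]),
                    hcl=hcl,
                    diagnosis=Diagnosis(row["diagnosis"]),
                )
            )
        except (ValueError, QuantError) as exc:
            raise QuantError(f"cohort CSV row {rownum}: {exc}") from exc
    return records


def write_phantom_png(
    image: PlanarImage,
    path: str | Path,
    params: PhantomParams | None = None,
    grade: int | None = None,
) -> None:
    """16-bit unsigned PNG plus a JSON sidecar with generator parameters."""
    path = Path(path)
    counts = image.counts
    if counts.max() > np.iinfo(np.uint16).max:
        raise QuantError("counts exceed 16-bit range; rescale before writing PNG")
    iio.imwrite(path, counts.astype(np.uint16))
    sidecar = {
        "pixel_spacing_mm": image.pixel_spacing,
        "time_post_injection_h": image.time_post_injection,
        "projection": image.projection,
    }
    if params is not None:
        sidecar["phantom_params"] = dataclasses.asdict(params)
    if grade is not None:
        sidecar["grade"] = grade
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_phantom_png(path: str | Path) -> PlanarImage:
    """Read a 16-bit phantom PNG, applying its JSON sidecar if present."""
    path = Path(path)
    counts = np.asarray(iio.imread(path)).astype(np.int64)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PlanarImage(
        counts=counts,
        pixel_spacing=meta.get("pixel_spacing_mm", 4.42),
        time_post_injection=meta.get("time_post_injection_h", 3.0),
        projection=meta.get("projection", "anterior"),
    )


def write_planar_dicom(image: PlanarImage, path: str | Path) -> None:
    """Write counts as a DICOM secondary-capture-style NM planar image."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [image.pixel_spacing, image.pixel_spacing]
    ds.ImageComments = (
        f"projection={image.projection};"
        f"time_post_injection_h={image.time_post_injection}"
    )
    if image.counts.max() > np.iinfo(np.uint16).max:
        raise QuantError("counts exceed 16-bit range; rescale before writing DICOM")
    ds.PixelData = image.counts.astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_planar_dicom(path: str | Path) -> PlanarImage:
    """Read a planar NM DICOM into a count image.

    Extracts the pixel grid, pixel spacing and, when encoded in the
    comments, projection and post-injection time.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    counts = np.asarray(ds.pixel_array).astype(np.int64)
    spacing = 4.42
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    projection, tpi = "anterior", 3.0
    for token in str(getattr(ds, "ImageComments", "")).split(";"):
        if token.startswith("projection="):
            projection = token.split("=", 1)[1]
        elif token.startswith("time_post_injection_h="):
            tpi = float(token.split("=", 1)[1])
    return PlanarImage(
        counts=counts, pixel_spacing=spacing,
        time_post_injection=tpi, projection=projection,
    )


def read_planar_image(path: str | Path) -> PlanarImage:
    """Dispatch on suffix: .png (with sidecar), .dcm/.dicom, or .npy."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        return read_phantom_png(path)
    if suffix in (".dcm", ".dicom"):
        return read_planar_dicom(path)
    if suffix == ".npy":
        return PlanarImage(counts=np.load(path))
    raise QuantError(f"unsupported image format {suffix!r}")
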