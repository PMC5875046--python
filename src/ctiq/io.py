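"""Stack persistence: a portable raw-raster container and DICOM CT slices.

The portable container is a directory holding one little-endian int16 raster
per replicate (``replicate_000.raw`` ...) plus a JSON sidecar
(``stack.json``) with the matrix shape, pixel spacing, scan condition, seed
and layout name. HU values are rounded to the nearest integer on write, so
write -> read is lossless for integer-valued HU within the int16 range.

DICOM slices are written with RescaleSlope/RescaleIntercept (stored pixels =
HU - intercept) and both are honoured on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .simulate import ImageStack, ScanCondition

__all__ = ["read_dicom_stack", "read_stack", "write_dicom_stack", "write_stack"]

_SIDECAR = "stack.json"


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as int16 rasters + JSON sidecar; returns the directory."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    n, h, w = stack.images.shape
    for k in range(n):
        arr = np.clip(np.rint(stack.images[k]), -32768, 32767).astype("<i2")
        (d / f"replicate_{k:03d}.raw").write_bytes(arr.tobytes())
    sidecar = {
        "matrix": [n, h, w],
        "spacing_mm": stack.pixel_spacing_mm,
        "condition": {
            "algorithm": stack.condition.algorithm,
            "ctdi_vol": stack.condition.ctdi_vol,
            "pitch": stack.condition.pitch,
            "nominal_dose_label": stack.condition.nominal_dose_label,
        },
        "seed": stack.seed,
        "layout": stack.layout_name,
        "model": stack.model_name,
        "dtype": "int16",
        "byte_order": "little",
    }
    (d / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return d


def read_stack(path) -> ImageStack:
    """Read a portable-container stack back into memory."""
    d = Path(path)
    try:
        sidecar = json.loads((d / _SIDECAR).read_text())
        n, h, w = sidecar["matrix"]
        spacing = float(sidecar["spacing_mm"])
        cond = ScanCondition(**sidecar["condition"])
    except (KeyError, TypeError, json.JSONDecodeError) as e:
        raise ValueError(f"malformed stack sidecar in {d}: {e}") from e
    images = np.empty((n, h, w))
    for k in range(n):
        raw = (d / f"replicate_{k:03d}.raw").read_bytes()
        if len(raw) != h * w * 2:
            raise ValueError(f"replicate {k}: raster size does not match sidecar matrix")
        images[k] = np.frombuffer(raw, dtype="<i2").reshape(h, w)
    return ImageStack(
        images=images,
        pixel_spacing_mm=spacing,
        condition=cond,
        seed=int(sidecar.get("seed", 0)),
        layout_name=sidecar.get("layout", ""),
        model_name=sidecar.get("model", ""),
    )


def write_dicom_stack(stack: ImageStack, path) -> Path:
    """Write each replicate as a CT DICOM slice (RescaleIntercept -1024)."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    intercept = -1024.0
    for k in range(stack.n_replicates):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.SeriesDescription = (
            f"{stack.condition.algorithm} {stack.condition.ctdi_vol:g}mGy "
            f"pitch {stack.condition.pitch:g}"
        )
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = stack.shape
        ds.PixelSpacing = [stack.pixel_spacing_mm, stack.pixel_spacing_mm]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0  # unsigned stored values
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        stored = np.clip(np.rint(stack.images[k]) - intercept, 0, 65535).astype("<u2")
        ds.PixelData = stored.tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(d / f"slice_{k:03d}.dcm", ds, enforce_file_format=True)
    return d


def read_dicom_stack(path, condition: ScanCondition | None = None) -> ImageStack:
    """Read a directory of CT slices, honouring RescaleSlope/Intercept."""
    d = Path(path)
    files = sorted(d.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files in {d}")
    images, spacing = [], None
    for f in files:
        ds = pydicom.dcmread(f)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        images.append(ds.pixel_array.astype(np.float64) * slope + intercept)
        sp = float(ds.PixelSpacing[0])
        if spacing is None:
            spacing = sp
        elif not np.isclose(sp, spacing):
            raise ValueError("inconsistent pixel spacing across replicates")
    if condition is None:
        condition = ScanCondition("FBP", 24.0)
    return ImageStack(
        images=np.stack(images),
        pixel_spacing_mm=spacing,
        condition=condition,
        seed=0,
    )
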