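"""DICOM image/mask I/O, ROI extraction, normalization and grey-level discretization.

A study unit is a pair of single-frame 8-bit greyscale DICOM files — the
original ultrasound frame and a binary region-of-interest (ROI) mask drawn
over the ovary — stored in a ``<machine>/<patient>/<side>/<plane>/`` folder
hierarchy. All texture features downstream operate on the masked pixels
after rescaling them to the full [0, 255] range and binning them into a
fixed number of grey levels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian
from scipy import ndimage

__all__ = [
    "UltrasoundFrame",
    "RoiMask",
    "NormalizedRoi",
    "DiscretizedRoi",
    "PairingError",
    "MaskError",
    "read_dicom_pair",
    "write_dicom_pair",
    "normalize_roi",
    "discretize",
    "read_manifest",
]

SIDES = ("left", "right")
PLANES = ("longitudinal", "coronal")

#: level value reserved for pixels outside the ROI in a DiscretizedRoi
OUTSIDE = 0


class PairingError(ValueError):
    """Image and mask files cannot be combined (missing file, shape mismatch)."""


class MaskError(ValueError):
    """ROI mask violates its contract (empty, too small, or fragmented)."""


@dataclass(frozen=True)
class UltrasoundFrame:
    """Single 2D greyscale ultrasound frame with spacing and hierarchy tags.

    Attributes
    ----------
    pixels : ndarray
        2D array of grey values in [0, 255] (float or uint8).
    pixel_spacing : tuple of float
        Physical size of one pixel as (row, col) in millimetres.
    machine, patient_id, side, plane : str
        Hierarchy tags: scanner label, patient label, ovary side
        (``left``/``right``), scan plane (``longitudinal``/``coronal``).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    machine: str = ""
    patient_id: str = ""
    side: str = ""
    plane: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite pixels")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    def with_tags(self, **tags) -> "UltrasoundFrame":
        return replace(self, **tags)


@dataclass(frozen=True)
class RoiMask:
    """Binary ROI mask; must be a single 4-connected blob of >= 16 pixels."""

    mask: np.ndarray

    MIN_PIXELS = 16

    def __post_init__(self):
        m = np.asarray(self.mask).astype(bool)
        n = int(m.sum())
        if n == 0:
            raise MaskError("mask is empty")
        if n < self.MIN_PIXELS:
            raise MaskError(f"mask has {n} pixels, needs >= {self.MIN_PIXELS}")
        _, ncomp = ndimage.label(m)  # default structure = 4-connectivity
        if ncomp != 1:
            raise MaskError(f"mask has {ncomp} 4-connected components, expected 1")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class NormalizedRoi:
    """Masked pixels rescaled so the ROI histogram spans [0, 255].

    ``values`` is a float image that equals the rescaled grey level on the
    mask and 0 outside it; geometry (mask, spacing) travels along so texture
    and fractal code never needs the original frame.
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_spacing: tuple[float, float]

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class DiscretizedRoi:
    """Integer grey levels 1..n_levels on the mask, OUTSIDE (0) elsewhere."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        lv = np.asarray(self.levels)
        mask = lv != OUTSIDE if self.mask is None else np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "levels", lv.astype(np.int64))
        object.__setattr__(self, "mask", mask)


def normalize_roi(frame: UltrasoundFrame, roi: RoiMask) -> NormalizedRoi:
    """Rescale the masked pixel values linearly onto [0, 255].

    v' = 255 * (v - min) / (max - min) over masked pixels only. A constant
    ROI (max == min) maps to all zeros, preserving "dark" semantics while
    avoiding division by zero. Idempotent on already-normalized ROIs.
    """
    if frame.pixels.shape != roi.mask.shape:
        raise PairingError(
            f"frame shape {frame.pixels.shape} != mask shape {roi.mask.shape}"
        )
    v = frame.pixels.astype(np.float64)
    sel = roi.mask
    vmin = v[sel].min()
    vmax = v[sel].max()
    out = np.zeros_like(v)
    if vmax > vmin:
        out[sel] = 255.0 * (v[sel] - vmin) / (vmax - vmin)
    return NormalizedRoi(values=out, mask=sel, pixel_spacing=frame.pixel_spacing)


def discretize(roi: NormalizedRoi, n_levels: int = 32) -> DiscretizedRoi:
    """Bin normalized values into ``n_levels`` equal-width grey levels.

    level = min(n_levels, floor(v' * n_levels / 256) + 1), i.e. uniform bins
    over [0, 256) with the top edge (255) inclusive in the last level.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    levels = np.full(roi.values.shape, OUTSIDE, dtype=np.int64)
    v = roi.values[roi.mask]
    lv = np.floor(v * n_levels / 256.0).astype(np.int64) + 1
    np.clip(lv, 1, n_levels, out=lv)
    levels[roi.mask] = lv
    return DiscretizedRoi(levels=levels, n_levels=n_levels, mask=roi.mask)


# ---------------------------------------------------------------------------
# DICOM round trip


def _make_dataset(pixels: np.ndarray, spacing, tags: dict, uid_stub: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = uid_stub
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    ds.SOPInstanceUID = uid_stub
    ds.Modality = "US"
    ds.PatientID = tags.get("patient_id", "")
    ds.PatientName = tags.get("patient_id", "")
    ds.StationName = tags.get("machine", "")[:16]
    ds.ManufacturerModelName = tags.get("machine", "")
    ds.ImageLaterality = {"left": "L", "right": "R"}.get(tags.get("side", ""), "")
    ds.SeriesDescription = tags.get("plane", "")
    ds.ImageComments = tags.get("kind", "original")
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [f"{spacing[0]:.6f}", f"{spacing[1]:.6f}"]
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(pixels.astype(np.uint8)).tobytes()
    return ds


def _stable_uid(*parts) -> str:
    """Deterministic DICOM UID from string parts (2.25.<decimal hash>)."""
    import hashlib

    h = hashlib.sha1("/".join(str(p) for p in parts).encode()).hexdigest()[:30]
    return "2.25." + str(int(h, 16))


def write_dicom_pair(
    frame: UltrasoundFrame, roi: RoiMask, path_image: str, path_mask: str
) -> None:
    """Write an (image, mask) pair as 8-bit monochrome single-frame DICOM.

    Mask pixels are written as 0/255. UIDs are derived deterministically
    from the hierarchy tags so identical cohorts produce identical bytes.
    """
    tags = {
        "machine": frame.machine,
        "patient_id": frame.patient_id,
        "side": frame.side,
        "plane": frame.plane,
    }
    key = (frame.machine, frame.patient_id, frame.side, frame.plane)
    img = _make_dataset(
        np.clip(np.round(frame.pixels), 0, 255),
        frame.pixel_spacing,
        {**tags, "kind": "original"},
        _stable_uid(*key, "original"),
    )
    msk = _make_dataset(
        roi.mask.astype(np.uint8) * 255,
        frame.pixel_spacing,
        {**tags, "kind": "mask"},
        _stable_uid(*key, "mask"),
    )
    for ds, path in ((img, path_image), (msk, path_mask)):
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        ds.save_as(path, enforce_file_format=True)


def _tags_from_path(path: str) -> dict:
    """Recover machine/patient/side/plane from the folder hierarchy."""
    parts = os.path.normpath(os.path.abspath(path)).split(os.sep)
    out = {}
    if len(parts) >= 5:
        machine, patient, side, plane = parts[-5:-1]
        if side in SIDES and plane in PLANES:
            out = {
                "machine": machine,
                "patient_id": patient,
                "side": side,
                "plane": plane,
            }
    return out


def read_dicom_pair(path_image: str, path_mask: str) -> tuple[UltrasoundFrame, RoiMask]:
    """Read an original/mask DICOM pair into domain objects.

    Tags are taken from DICOM fields when present, falling back to the
    ``<machine>/<patient>/<side>/<plane>/`` folder layout. The mask is
    binarized at > 0. Raises :class:`PairingError` on shape mismatch and
    :class:`MaskError` on an empty or fragmented mask.
    """
    dsi = pydicom.dcmread(path_image)
    dsm = pydicom.dcmread(path_mask)
    img = dsi.pixel_array
    msk = dsm.pixel_array
    if img.shape != msk.shape:
        raise PairingError(f"image shape {img.shape} != mask shape {msk.shape}")
    hier = _tags_from_path(path_image)
    spacing = tuple(float(s) for s in getattr(dsi, "PixelSpacing", [1.0, 1.0]))
    frame = UltrasoundFrame(
        pixels=img.astype(np.float64),
        pixel_spacing=spacing,
        machine=str(getattr(dsi, "ManufacturerModelName", "") or hier.get("machine", "")),
        patient_id=str(getattr(dsi, "PatientID", "") or hier.get("patient_id", "")),
        side={"L": "left", "R": "right"}.get(
            str(getattr(dsi, "ImageLaterality", "")), hier.get("side", "")
        ),
        plane=str(getattr(dsi, "SeriesDescription", "") or hier.get("plane", "")),
    )
    return frame, RoiMask(mask=msk > 0)


def read_manifest(path: str) -> pd.DataFrame:
    """Read a cohort manifest CSV and check the required columns."""
    df = pd.read_csv(path, dtype={"patient_id": str, "image_id": str})
    required = {
        "image_id",
        "path_image",
        "path_mask",
        "machine",
        "patient_id",
        "side",
        "plane",
        "label",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
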