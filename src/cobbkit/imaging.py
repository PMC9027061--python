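"""Radiograph I/O and viewing transforms.

Loads DICOM full-length spine radiographs and provides the two viewing
aids a Cobb measurement tool needs — window/level contrast adjustment
and region-of-interest zoom — as pure functions with exact coordinate
bookkeeping.  The central safety property of computer-aided measurement
is that viewing transforms never touch measured geometry: landmarks
live in source-image coordinates and contrast changes only pixel
values, so no display setting can alter a reported angle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .geometry import Landmark

__all__ = [
    "Radiograph",
    "RoiTransform",
    "RoiMapping",
    "RadiographFormatError",
    "load_radiograph",
    "write_radiograph_dicom",
    "adjust_contrast",
    "crop_zoom",
]

logger = logging.getLogger(__name__)


class RadiographFormatError(ValueError):
    """Raised when a file cannot be read as a radiograph."""


@dataclass(frozen=True)
class Radiograph:
    """A 2-D radiograph: intensity grid plus pixel-spacing metadata.

    ``pixel_spacing`` is (row mm/px, col mm/px) or ``None`` when the
    source carries no spacing information.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixel grid must be 2-D and non-empty")
        if self.pixel_spacing is not None:
            r, c = self.pixel_spacing
            if not (r > 0 and c > 0):
                raise ValueError("pixel spacing must be strictly positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiTransform:
    """A crop-and-zoom view: crop corner, extent and magnification.

    ``origin`` is the top-left corner of the region of interest in
    source coordinates; ``rows``/``cols`` give its extent (``None``
    means "to the image edge"); ``factor`` is the zoom magnification.
    """

    origin: Landmark
    factor: float
    rows: int | None = None
    cols: int | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.factor) and self.factor > 0):
            raise ValueError("zoom factor must be finite and > 0")


class RoiMapping:
    """Bijective mapping between source and zoomed-view coordinates.

    ``map_to`` sends a source-space point into the zoomed view;
    ``map_back`` inverts it exactly for continuous coordinates.
    """

    def __init__(self, origin: Landmark, factor: float):
        self.origin = origin
        self.factor = factor

    def map_to(self, p: Landmark) -> Landmark:
        return Landmark(
            (p.x - self.origin.x) * self.factor,
            (p.y - self.origin.y) * self.factor,
        )

    def map_back(self, p: Landmark) -> Landmark:
        return Landmark(
            p.x / self.factor + self.origin.x,
            p.y / self.factor + self.origin.y,
        )


def load_radiograph(path: str | Path) -> Radiograph:
    """Read a DICOM file into a :class:`Radiograph`.

    Reads pixel data and the standard pixel-spacing tags
    (``PixelSpacing``, falling back to ``ImagerPixelSpacing``).  A file
    without spacing metadata loads with ``pixel_spacing=None`` and a
    warning — angles are still measurable on square pixels, but
    physical distances are not.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several unrelated types
        raise RadiographFormatError(f"cannot read DICOM file {path}: {exc}") from exc
    try:
        pixels = np.asarray(ds.pixel_array)
    except Exception as exc:
        raise RadiographFormatError(f"{path} has no decodable pixel data") from exc
    if pixels.ndim != 2:
        raise RadiographFormatError(
            f"{path}: expected a single-frame greyscale image, got shape {pixels.shape}"
        )

    spacing = None
    tag = ds.get("PixelSpacing") or ds.get("ImagerPixelSpacing")
    if tag is not None:
        spacing = (float(tag[0]), float(tag[1]))
    else:
        msg = f"{path.name}: no pixel-spacing metadata; distances unavailable"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return Radiograph(pixels=pixels, pixel_spacing=spacing, source_id=path.name)


def write_radiograph_dicom(img: Radiograph, path: str | Path) -> Path:
    """Write a radiograph as a minimal greyscale DICOM file.

    Used by the phantom generator and round-trip tests; emits
    monochrome secondary-capture-style data with explicit VR.
    """
    path = Path(path)
    pixels = np.ascontiguousarray(img.pixels)
    if pixels.dtype != np.uint16:
        pixels = np.clip(pixels, 0, 65535).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if img.pixel_spacing is not None:
        ds.PixelSpacing = [str(img.pixel_spacing[0]), str(img.pixel_spacing[1])]
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def adjust_contrast(
    img: Radiograph, window: float, level: float, out_max: int = 255
) -> Radiograph:
    """Linear window/level contrast mapping.

    Intensities in [level - window/2, level + window/2] map linearly
    onto [0, out_max]; values outside clamp.  The mapping is monotone
    non-decreasing and touches only pixel values — geometry, spacing
    and landmark coordinates are untouched.  Output values are rounded
    half-up to integers (so level maps to the mid-grey ceil(out_max/2)).
    """
    if not window > 0:
        raise ValueError("window width must be > 0")
    lo = level - window / 2.0
    x = np.asarray(img.pixels, dtype=np.float64)
    y = np.clip((x - lo) / window, 0.0, 1.0) * out_max
    y = np.floor(y + 0.5)  # half-up, matching display LUT behaviour
    dtype = np.uint8 if out_max <= 255 else np.uint16
    return Radiograph(
        pixels=y.astype(dtype),
        pixel_spacing=img.pixel_spacing,
        source_id=img.source_id,
    )


def crop_zoom(
    img: Radiograph, t: RoiTransform, interpolation: str = "nearest"
) -> tuple[Radiograph, RoiMapping]:
    """Crop a region of interest and magnify it.

    Returns the enlarged view (for display) together with the exact
    coordinate mapping.  Landmarks picked in the view are converted
    with ``mapping.map_back`` and stored in source coordinates, so
    display interpolation (``"nearest"`` or ``"bilinear"``) never
    affects measurements; the only error a zoomed pick can carry is
    the view's own quantisation, which shrinks as 1/factor.
    """
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")
    r0 = int(np.floor(t.origin.y))
    c0 = int(np.floor(t.origin.x))
    r1 = img.rows if t.rows is None else r0 + t.rows
    c1 = img.cols if t.cols is None else c0 + t.cols
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, img.rows), min(c1, img.cols)
    if r1c <= r0c or c1c <= c0c:
        raise ValueError("region of interest does not intersect the image")

    roi = img.pixels[r0c:r1c, c0c:c1c]
    mapping = RoiMapping(origin=Landmark(float(c0c), float(r0c)), factor=t.factor)

    out_rows = max(1, int(round(roi.shape[0] * t.factor)))
    out_cols = max(1, int(round(roi.shape[1] * t.factor)))
    rr = np.arange(out_rows) / t.factor
    cc = np.arange(out_cols) / t.factor
    if interpolation == "nearest":
        ri = np.clip(np.floor(rr).astype(int), 0, roi.shape[0] - 1)
        ci = np.clip(np.floor(cc).astype(int), 0, roi.shape[1] - 1)
        view = roi[np.ix_(ri, ci)]
    else:
        roi_f = roi.astype(np.float64)
        r_lo = np.clip(np.floor(rr).astype(int), 0, roi.shape[0] - 1)
        r_hi = np.clip(r_lo + 1, 0, roi.shape[0] - 1)
        c_lo = np.clip(np.floor(cc).astype(int), 0, roi.shape[1] - 1)
        c_hi = np.clip(c_lo + 1, 0, roi.shape[1] - 1)
        wr = (rr - r_lo)[:, None]
        wc = (cc - c_lo)[None, :]
        view = (
            roi_f[np.ix_(r_lo, c_lo)] * (1 - wr) * (1 - wc)
            + roi_f[np.ix_(r_hi, c_lo)] * wr * (1 - wc)
            + roi_f[np.ix_(r_lo, c_hi)] * (1 - wr) * wc
            + roi_f[np.ix_(r_hi, c_hi)] * wr * wc
        )
        view = view.astype(roi.dtype)

    out = Radiograph(pixels=view, pixel_spacing=None, source_id=img.source_id)
    return out, mapping
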