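"""Image loading, micron-per-pixel calibration, and multi-image sessions.

All pixel coordinates in this package are 0-based ``(row, col)`` with the row
axis increasing downward, matching raster storage order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "FormatError",
    "CalibrationError",
    "RasterImage",
    "Calibration",
    "Session",
    "load_image",
    "read_mpp_metadata",
    "calibration_from_line",
    "pixel_distance",
    "area_to_physical",
]


class FormatError(ValueError):
    """Raised when an image file cannot be decoded."""


class CalibrationError(ValueError):
    """Raised for invalid or contradictory calibration inputs."""


@dataclass(frozen=True)
class Calibration:
    """Physical pixel scale.

    Attributes
    ----------
    mpp : float
        Microns per pixel (> 0).
    """

    mpp: float

    def __post_init__(self) -> None:
        if not (self.mpp > 0 and math.isfinite(self.mpp)):
            raise CalibrationError(f"mpp must be a positive finite number, got {self.mpp!r}")

    @property
    def area_factor(self) -> float:
        """Square microns per pixel; exactly ``mpp ** 2``."""
        return self.mpp * self.mpp


@dataclass
class RasterImage:
    """A decoded raster image: ``H x W`` grayscale or ``H x W x 3`` RGB uint8."""

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
            raise FormatError(
                f"expected HxW grayscale or HxWx3 RGB pixels, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError("image must have at least one row and one column")
        if arr.dtype != np.uint8:
            arr = _coerce_uint8(arr)
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def _coerce_uint8(arr: np.ndarray) -> np.ndarray:
    """Map common decoded dtypes onto the 0-255 range."""
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    if np.issubdtype(arr.dtype, np.integer):
        if arr.max(initial=0) > 255:
            # 16-bit sources: integer downscale, preserving full-range endpoints
            return (arr.astype(np.uint32) // 257).astype(np.uint8)
        return arr.astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        mx = float(np.nanmax(arr)) if arr.size else 0.0
        scale = 255.0 if mx <= 1.0 else 1.0
        return np.clip(np.round(arr * scale), 0, 255).astype(np.uint8)
    raise FormatError(f"unsupported pixel dtype {arr.dtype}")


_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp"}


def load_image(path: str | Path) -> RasterImage:
    """Decode a TIFF/PNG/JPEG/BMP file into a :class:`RasterImage`.

    Grayscale sources are kept single-channel; an alpha channel, if present,
    is dropped.

    Raises
    ------
    FormatError
        If the file is missing, unsupported, or cannot be decoded.
    """
    p = Path(path)
    if not p.is_file():
        raise FormatError(f"image file not found: {p}")
    if p.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format {p.suffix!r} for {p}")
    try:
        import imageio.v3 as iio

        arr = iio.imread(p)
    except FormatError:
        raise
    except Exception as exc:  # decoder errors vary per backend
        raise FormatError(f"cannot decode image {p}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RasterImage(pixels=arr, source_path=str(p))


# number adjacent to a "microns per pixel" phrasing, either order
_MPP_PATTERNS = (
    re.compile(
        r"(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*"
        r"(?:µm|um|microns?)\s*(?:/|\bper\b)\s*(?:px|pixel)",
        re.IGNORECASE,
    ),
    re.compile(
        r"(?:µm|um|microns?|mpp)\s*(?:/|\bper\b)?\s*(?:px|pixel)?s?\s*[:=]\s*"
        r"(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)",
        re.IGNORECASE,
    ),
)


def _mpp_from_text(text: str) -> Calibration | None:
    for pat in _MPP_PATTERNS:
        m = pat.search(text)
        if m:
            value = float(m.group(1))
            if value > 0:
                return Calibration(mpp=value)
    return None


def _rational(value: Any) -> float | None:
    if isinstance(value, tuple) and len(value) == 2:
        num, den = value
        return float(num) / float(den) if den else None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _mpp_from_resolution(xres: float, yres: float, unit: int) -> Calibration:
    if abs(xres - yres) > 0.01 * max(xres, yres):
        raise CalibrationError(
            f"anisotropic pixels unsupported: X resolution {xres} vs Y resolution {yres}"
        )
    res = (xres + yres) / 2.0
    if unit == 2:  # inch
        mpp = 25400.0 / res
    elif unit == 3:  # centimetre
        mpp = 10000.0 / res
    else:  # no absolute unit: conventional microscopy export, pixels per micron
        mpp = 1.0 / res
    return Calibration(mpp=mpp)


def read_mpp_metadata(path: str | Path) -> Calibration | None:
    """Extract a micron-per-pixel calibration from image metadata, if any.

    Checks, in order: TIFF X/Y-resolution tags (with their resolution unit;
    a unitless resolution is interpreted as pixels per micron), then a
    case-insensitive scan of the image description / text chunks for a number
    adjacent to a "microns per pixel" phrasing. Returns ``None`` when no
    calibration is recorded.

    Raises
    ------
    CalibrationError
        If X and Y resolutions disagree by more than 1% (anisotropic pixels).
    """
    p = Path(path)
    if not p.is_file():
        raise FormatError(f"image file not found: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(p) as tf:
            page = tf.pages[0]
            tags = page.tags
            xres = _rational(tags["XResolution"].value) if "XResolution" in tags else None
            yres = _rational(tags["YResolution"].value) if "YResolution" in tags else None
            unit = int(tags["ResolutionUnit"].value) if "ResolutionUnit" in tags else 1
            if xres and yres and xres > 0 and yres > 0 and (xres, yres) != (1.0, 1.0):
                return _mpp_from_resolution(xres, yres, unit)
            desc = page.description or ""
            return _mpp_from_text(desc)
    # PNG text chunks / JPEG comments via Pillow
    from PIL import Image

    try:
        with Image.open(p) as im:
            parts = [str(v) for v in im.info.values() if isinstance(v, (str, bytes))]
    except Exception as exc:
        raise FormatError(f"cannot read metadata from {p}: {exc}") from exc
    text = " ".join(x.decode("utf-8", "ignore") if isinstance(x, bytes) else x for x in parts)
    return _mpp_from_text(text)


def calibration_from_line(length_pixels: float, length_microns: float) -> Calibration:
    """Calibration from a line of known physical length.

    ``mpp = length_microns / length_pixels``.
    """
    if not (length_pixels > 0):
        raise CalibrationError(f"line length in pixels must be > 0, got {length_pixels}")
    if not (length_microns > 0):
        raise CalibrationError(f"line length in microns must be > 0, got {length_microns}")
    return Calibration(mpp=length_microns / length_pixels)


def pixel_distance(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Euclidean distance between two (row, col) points, in pixels."""
    return math.hypot(p2[0] - p1[0], p2[1] - p1[1])


def area_to_physical(pixel_count: int, cal: Calibration) -> float:
    """Convert a pixel count to square microns via the calibration."""
    if pixel_count < 0:
        raise ValueError(f"pixel_count must be >= 0, got {pixel_count}")
    return pixel_count * cal.area_factor


@dataclass
class _SessionEntry:
    image: RasterImage
    calibration: Calibration | None = None
    results: dict[str, Any] = field(default_factory=dict)


class Session:
    """Ordered store of images with their calibrations and saved results.

    Every analysis product can be stored under its image id and retrieved
    later unchanged, so multiple images can be worked on without losing state.
    """

    def __init__(self) -> None:
        self._entries: dict[str, _SessionEntry] = {}

    def add_image(
        self, image_id: str, image: RasterImage, calibration: Calibration | None = None
    ) -> None:
        if image_id in self._entries:
            raise KeyError(f"image id {image_id!r} already present in session")
        self._entries[image_id] = _SessionEntry(image=image, calibration=calibration)

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def image_ids(self) -> list[str]:
        return list(self._entries)

    def image(self, image_id: str) -> RasterImage:
        return self._entries[image_id].image

    def calibration(self, image_id: str) -> Calibration | None:
        return self._entries[image_id].calibration

    def set_calibration(self, image_id: str, cal: Calibration) -> None:
        self._entries[image_id].calibration = cal

    def store_result(self, image_id: str, key: str, value: Any) -> None:
        self._entries[image_id].results[key] = value

    def result(self, image_id: str, key: str) -> Any:
        return self._entries[image_id].results[key]

    def results(self, image_id: str) -> dict[str, Any]:
        return dict(self._entries[image_id].results)
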