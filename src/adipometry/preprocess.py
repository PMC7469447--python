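"""Image conditioning ahead of segmentation.

Haze and dot-noise removal, grayscale conversion, thresholding, border-line
thickening, and the export/import round trip for manual border correction in
an external paint program.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_calibration import RasterImage

__all__ = [
    "PreprocessParams",
    "MaskShapeError",
    "to_grayscale",
    "dehaze",
    "denoise",
    "binarize",
    "thicken_borders",
    "export_for_edit",
    "import_edited",
]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)

_LOSSY_SUFFIXES = {".jpg", ".jpeg"}


class MaskShapeError(ValueError):
    """Raised when an imported mask does not match the expected image shape."""


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs for the detection pipeline.

    ``threshold`` is either an integer in 0-255 or the string ``"auto"``
    (Otsu). ``invert`` flips foreground polarity for stains whose cell
    interiors are dark. ``border_thickness`` is an erosion radius in pixels.
    """

    dehaze_strength: float = 0.0
    denoise_radius: int = 0
    threshold: int | str = "auto"
    border_thickness: int = 0
    invert: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.dehaze_strength <= 1.0):
            raise ValueError(f"dehaze_strength must be in [0, 1], got {self.dehaze_strength}")
        if self.denoise_radius < 0:
            raise ValueError(f"denoise_radius must be >= 0, got {self.denoise_radius}")
        if self.border_thickness < 0:
            raise ValueError(f"border_thickness must be >= 0, got {self.border_thickness}")
        if self.threshold != "auto":
            t = int(self.threshold)
            if not (0 <= t <= 255):
                raise ValueError(f"threshold must be 'auto' or in 0..255, got {self.threshold}")


def to_grayscale(img: RasterImage) -> RasterImage:
    """Luminance conversion: ``round(0.299 R + 0.587 G + 0.114 B)``.

    Grayscale input is returned unchanged.
    """
    if not img.is_rgb:
        return img
    rgb = img.pixels.astype(np.float64)
    gray = rgb[:, :, 0] * GRAY_WEIGHTS[0] + rgb[:, :, 1] * GRAY_WEIGHTS[1] + rgb[:, :, 2] * GRAY_WEIGHTS[2]
    return RasterImage(np.round(gray).astype(np.uint8), source_path=img.source_path)


def dehaze(img: RasterImage, strength: float) -> RasterImage:
    """Remove a veiling uniform brightness (dark-channel-prior style).

    Atmospheric light ``A`` is estimated from the brightest pixels of the
    per-pixel channel-minimum map; transmission is
    ``t = 1 - strength * dark/A`` floored at 0.1; the recovered radiance
    ``(I - A)/t + A`` is clipped back to [0, 255]. ``strength`` 0 is the
    identity.
    """
    if not (0.0 <= strength <= 1.0):
        raise ValueError(f"strength must be in [0, 1], got {strength}")
    if strength == 0.0:
        return RasterImage(img.pixels.copy(), source_path=img.source_path)
    arr = img.pixels.astype(np.float64)
    dark = arr.min(axis=2) if img.is_rgb else arr
    # atmospheric light: mean intensity over the brightest 0.1% of the dark channel
    n_top = max(1, int(dark.size * 0.001))
    flat = dark.ravel()
    top_idx = np.argpartition(flat, -n_top)[-n_top:]
    a_light = max(float(flat[top_idx].mean()), 1.0)
    t = 1.0 - strength * (dark / a_light)
    t = np.maximum(t, 0.1)
    if img.is_rgb:
        t = t[:, :, None]
    out = (arr - a_light) / t + a_light
    return RasterImage(np.clip(np.round(out), 0, 255).astype(np.uint8), source_path=img.source_path)


def denoise(img: RasterImage, radius: int) -> RasterImage:
    """Median filter with a square window of side ``2 * radius + 1``.

    Removes isolated dark/bright specks up to ``radius`` in size while
    retaining lines wider than ``2 * radius``. Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return RasterImage(img.pixels.copy(), source_path=img.source_path)
    k = 2 * radius + 1
    size = (k, k, 1) if img.is_rgb else (k, k)
    out = ndimage.median_filter(img.pixels, size=size)
    return RasterImage(out, source_path=img.source_path)


def binarize(gray: RasterImage, threshold: int | str = "auto", invert: bool = False) -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask.

    Foreground is ``gray > T`` (XOR ``invert``); ``"auto"`` picks the Otsu
    threshold maximizing between-class variance. By convention cell interiors
    end up foreground; use ``invert`` for dark-interior stains.
    """
    if gray.is_rgb:
        raise ValueError("binarize expects a grayscale image; call to_grayscale first")
    pix = gray.pixels
    if threshold == "auto":
        if pix.min() == pix.max():
            t = int(pix.flat[0])  # degenerate flat image: everything background
        else:
            from skimage.filters import threshold_otsu

            t = threshold_otsu(pix)
    else:
        t = int(threshold)
    mask = pix > t
    return ~mask if invert else mask


def thicken_borders(mask: np.ndarray, thickness: int) -> np.ndarray:
    """Thicken separating border lines by eroding the foreground.

    Erosion uses a disc of radius ``thickness``; pixels outside the frame are
    treated as foreground so frame-touching cells are not eaten from the
    image edge. Greater thickness seals broken membranes (merging bridges of
    width <= 2*thickness are removed) at the cost of smaller measured areas.
    """
    if thickness < 0:
        raise ValueError(f"thickness must be >= 0, got {thickness}")
    if thickness == 0:
        return mask.copy()
    from skimage.morphology import disk

    footprint = disk(thickness).astype(bool)
    return ndimage.binary_erosion(mask, structure=footprint, border_value=1)


def export_for_edit(mask: np.ndarray, path: str | Path) -> Path:
    """Write the mask as an 8-bit image for hand correction in a paint tool.

    Interiors are written as 255, borders/background as 0. A warning is
    emitted for lossy formats (JPEG), which will corrupt the round trip.
    """
    from PIL import Image

    p = Path(path)
    if p.suffix.lower() in _LOSSY_SUFFIXES:
        warnings.warn(
            f"{p.suffix} is lossy; the edited mask will not round-trip exactly",
            stacklevel=2,
        )
    Image.fromarray(mask.astype(np.uint8) * 255).save(p)
    return p


def import_edited(path: str | Path, expected_shape: tuple[int, int]) -> np.ndarray:
    """Read back a hand-edited mask image and re-binarize it.

    Any pixel darker than 128 becomes border/background, so strokes drawn in
    black become separating borders. The image must match ``expected_shape``.
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    if arr.shape != tuple(expected_shape):
        raise MaskShapeError(
            f"edited mask shape {arr.shape} does not match expected {tuple(expected_shape)}"
        )
    return arr >= 128
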