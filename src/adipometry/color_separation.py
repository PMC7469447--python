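"""Colour-range area quantification and fluorescent channel splitting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_calibration import Calibration, RasterImage

__all__ = [
    "ColorRange",
    "ChannelSelection",
    "PRESET_RANGES",
    "mask_by_rgb_range",
    "area_percentage",
    "extract_channels",
    "convert_black_white",
]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}
_CHANNEL_LETTER = {"r": "red", "g": "green", "b": "blue"}


@dataclass(frozen=True)
class ColorRange:
    """Inclusive per-channel intensity intervals (a box in RGB space)."""

    r_lo: int = 0
    r_hi: int = 255
    g_lo: int = 0
    g_hi: int = 255
    b_lo: int = 0
    b_hi: int = 255

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            lo = getattr(self, f"{name}_lo")
            hi = getattr(self, f"{name}_hi")
            if not (0 <= lo <= 255 and 0 <= hi <= 255):
                raise ValueError(f"{name} bounds must lie in 0..255, got ({lo}, {hi})")
            if lo > hi:
                raise ValueError(f"{name}_lo {lo} exceeds {name}_hi {hi}")

    @classmethod
    def from_string(cls, text: str) -> "ColorRange":
        """Parse ``"R_LO:R_HI,G_LO:G_HI,B_LO:B_HI"``."""
        parts = text.split(",")
        if len(parts) != 3:
            raise ValueError(f"expected three comma-separated lo:hi pairs, got {text!r}")
        bounds = []
        for part in parts:
            lo, _, hi = part.partition(":")
            bounds.extend([int(lo), int(hi)])
        return cls(*bounds)


#: Documented tool defaults for common stains; not measured constants.
PRESET_RANGES: dict[str, ColorRange] = {
    "reddish-brown": ColorRange(90, 200, 30, 110, 20, 90),
    "eosin-pink": ColorRange(180, 255, 100, 200, 140, 230),
}


@dataclass(frozen=True)
class ChannelSelection:
    """Non-empty subset of the red/green/blue display channels."""

    channels: frozenset[str]

    def __post_init__(self) -> None:
        names = frozenset(self.channels)
        if not names:
            raise ValueError("channel selection must be non-empty")
        unknown = names - set(_CHANNEL_INDEX)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        object.__setattr__(self, "channels", names)

    @classmethod
    def from_string(cls, text: str) -> "ChannelSelection":
        """Parse a compact letter selection such as ``"rb"`` or ``"g"``."""
        try:
            return cls(frozenset(_CHANNEL_LETTER[ch] for ch in text.lower()))
        except KeyError as exc:
            raise ValueError(f"invalid channel letter in {text!r} (use r, g, b)") from exc

    def __iter__(self):
        return iter(sorted(self.channels, key=lambda n: _CHANNEL_INDEX[n]))


def mask_by_rgb_range(img: RasterImage, color_range: ColorRange) -> np.ndarray:
    """Boolean mask of pixels whose R, G and B all lie within the range."""
    if not img.is_rgb:
        raise ValueError("mask_by_rgb_range expects an RGB image")
    px = img.pixels
    cr = color_range
    return (
        (px[:, :, 0] >= cr.r_lo) & (px[:, :, 0] <= cr.r_hi)
        & (px[:, :, 1] >= cr.g_lo) & (px[:, :, 1] <= cr.g_hi)
        & (px[:, :, 2] >= cr.b_lo) & (px[:, :, 2] <= cr.b_hi)
    )


def area_percentage(
    mask: np.ndarray, cal: Calibration | None = None
) -> tuple[float, float | None]:
    """Foreground share of the image in percent, plus square microns if calibrated."""
    fg = int(np.count_nonzero(mask))
    pct = 100.0 * fg / mask.size
    um2 = fg * cal.area_factor if cal is not None else None
    return pct, um2


def extract_channels(
    img: RasterImage,
    selection: ChannelSelection,
    display_threshold: int = 0,
) -> tuple[RasterImage, dict[str, np.ndarray]]:
    """Split an RGB image into uniform-intensity channel views.

    Each selected channel yields a mask of pixels whose intensity exceeds
    ``display_threshold``; the rendering paints those pixels at full
    intensity in that channel and leaves everything else black, so the
    displayed intensity is the same everywhere a channel is present. The
    rendering is a normal image and can be reloaded into a session.
    """
    if not img.is_rgb:
        raise ValueError("extract_channels expects an RGB image")
    if not (0 <= display_threshold <= 255):
        raise ValueError(f"display_threshold must be in 0..255, got {display_threshold}")
    masks: dict[str, np.ndarray] = {}
    rendering = np.zeros_like(img.pixels)
    for name in selection:
        idx = _CHANNEL_INDEX[name]
        mask = img.pixels[:, :, idx] > display_threshold
        masks[name] = mask
        rendering[:, :, idx][mask] = 255
    return RasterImage(rendering, source_path=img.source_path), masks


def convert_black_white(mask: np.ndarray) -> RasterImage:
    """Render a mask as a grayscale image: foreground 255, background 0."""
    return RasterImage(np.asarray(mask, dtype=bool).astype(np.uint8) * 255)
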