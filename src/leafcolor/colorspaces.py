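"""Deterministic conversions between 8-bit sRGB and the HSV, CIE L*a*b*
and chromatic (normalized) rgb coordinate systems.

Conventions
-----------
* Hue is expressed in **degrees on [0, 360)**, not the half-range scale of
  some 8-bit image libraries.  This matters because the Dark Green Color
  Index divides H by 60 and is only meaningful on the degree scale.
* Achromatic pixels (S = 0) report H = 0.
* L*a*b* uses the D65 white point and the 2° standard observer with the
  standard sRGB decompanding curve (delegated to :func:`skimage.color.rgb2lab`).
* Chromatic rgb are channel fractions r = R/(R+G+B) etc.; a black pixel has
  no defined chromaticity and is returned as a flagged undefined record.

Scalar dataclass helpers operate on one pixel; the ``*_array`` functions are
vectorized over ``(..., 3)`` uint8 rasters and are what the imaging module
uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab


@dataclass(frozen=True)
class PixelColor:
    """An 8-bit sRGB triplet, each channel in [0, 255]."""

    R: int
    G: int
    B: int

    def __post_init__(self) -> None:
        for name in ("R", "G", "B"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"channel {name}={v} outside [0, 255]")


@dataclass(frozen=True)
class HsvColor:
    """Hue in degrees [0, 360); saturation and value as fractions in [0, 1]."""

    H: float
    S: float
    V: float


@dataclass(frozen=True)
class LabColor:
    """CIE L*a*b* under D65 / 2° observer. L in [0, 100]; a, b signed."""

    L: float
    a: float
    b: float


@dataclass(frozen=True)
class ChromaticRgb:
    """Channel fractions of the channel sum; undefined for a black pixel."""

    r: float
    g: float
    b: float
    defined: bool = True


# ---------------------------------------------------------------------------
# vectorized conversions


def rgb_to_hsv_array(rgb: np.ndarray) -> np.ndarray:
    """Hexcone HSV for an ``(..., 3)`` array of 8-bit sRGB values.

    Returns a float array of the same leading shape with channels
    (H degrees [0, 360), S [0, 1], V [0, 1]).  Achromatic inputs get H = 0.
    """
    arr = np.asarray(rgb, dtype=np.float64) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    v = arr.max(axis=-1)
    c = v - arr.min(axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, c / v, 0.0)
        hp = np.where(
            c > 0,
            np.select(
                [v == r, v == g],
                [(g - b) / np.where(c > 0, c, 1.0),
                 (b - r) / np.where(c > 0, c, 1.0) + 2.0],
                (r - g) / np.where(c > 0, c, 1.0) + 4.0,
            ),
            0.0,
        )
    h = (hp * 60.0) % 360.0
    h = np.where(c > 0, h, 0.0)
    return np.stack([h, s, v], axis=-1)


def hsv_to_rgb_array(hsv: np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion back to 8-bit sRGB (rounded uint8).

    Exactly recovers any triplet produced by :func:`rgb_to_hsv_array`.
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    c = v * s
    hp = (h % 360.0) / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    zeros = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r1 = np.choose(sector, [c, x, zeros, zeros, x, c])
    g1 = np.choose(sector, [x, c, c, x, zeros, zeros])
    b1 = np.choose(sector, [zeros, zeros, x, c, c, x])
    m = v - c
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1) * 255.0
    return np.rint(rgb).astype(np.uint8)


def rgb_to_lab_array(rgb: np.ndarray) -> np.ndarray:
    """CIE L*a*b* (D65, 2°) for an ``(..., 3)`` array of 8-bit sRGB values."""
    arr = np.asarray(rgb, dtype=np.float64) / 255.0
    return rgb2lab(arr)


def normalize_rgb_array(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chromatic rgb fractions and a boolean ``defined`` mask.

    Black pixels (R+G+B = 0) have no chromaticity; their fractions are
    returned as NaN and flagged False.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    total = arr.sum(axis=-1, keepdims=True)
    defined = total[..., 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, arr / total, np.nan)
    return frac, defined


# ---------------------------------------------------------------------------
# scalar (single-pixel) API


def srgb_to_hsv(pixel: PixelColor) -> HsvColor:
    """Standard hexcone conversion; H in degrees, H := 0 when S = 0."""
    h, s, v = rgb_to_hsv_array(np.array([pixel.R, pixel.G, pixel.B]))
    return HsvColor(float(h), float(s), float(v))


def srgb_to_lab(pixel: PixelColor) -> LabColor:
    """sRGB decompanding → XYZ (D65) → CIE L*a*b*, 2° observer."""
    lab = rgb_to_lab_array(np.array([pixel.R, pixel.G, pixel.B]))
    return LabColor(float(lab[0]), float(lab[1]), float(lab[2]))


def normalize_rgb(pixel: PixelColor) -> ChromaticRgb:
    """Channel fractions r, g, b of the channel sum.

    A black input is degenerate and yields a flagged undefined record rather
    than raising.
    """
    total = pixel.R + pixel.G + pixel.B
    if total == 0:
        return ChromaticRgb(float("nan"), float("nan"), float("nan"), defined=False)
    return ChromaticRgb(pixel.R / total, pixel.G / total, pixel.B / total)


def circular_mean_degrees(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Vector mean of angles in degrees, mapped to [0, 360).

    Used for averaging hue over a leaf: the arithmetic mean of angles is
    meaningless across the 0/360 wrap.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    if weights is None:
        s, c = np.sin(a).mean(), np.cos(a).mean()
    else:
        w = np.asarray(weights, dtype=np.float64)
        s, c = np.average(np.sin(a), weights=w), np.average(np.cos(a), weights=w)
    h = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    return 0.0 if h >= 360.0 else h  # fp wrap: tiny negative angles mod to 360.0
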