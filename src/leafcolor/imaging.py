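"""Leaf photograph handling: loading, segmentation from a near-white
background, and averaging of the 12 color features over the leaf mask.

Segmentation model: the imaging rig photographs a single excised leaf on a
matte white stage, so background pixels are bright and nearly achromatic
(high V, low S) while leaf pixels are saturated.  The default classifier
marks background as (S below an Otsu threshold on the saturation channel)
AND (V above a configurable floor), takes the complement, applies
morphological closing and hole filling, and keeps the largest connected
component.  A minimum component size (default 5000 pixels) guards against
debris being mistaken for a leaf.

Feature averaging is mean-then-convert-free: HSV and L*a*b* are computed
per pixel and then averaged (hue circularly, as a vector mean), not
converted from the mean RGB triplet.  Chromatic rgb fractions are averaged
over per-pixel fractions with black pixels excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle

from .colorspaces import (
    circular_mean_degrees,
    normalize_rgb_array,
    rgb_to_hsv_array,
    rgb_to_lab_array,
)

#: column order of the feature table
FEATURE_COLUMNS = [
    "leaf_id", "pixel_count",
    "R", "G", "B", "H", "S", "V", "L", "a", "b", "r", "g", "b_frac",
]


class NoLeafFoundError(ValueError):
    """Segmentation found no foreground at all."""


class MinPixelCountError(ValueError):
    """Largest candidate region is smaller than the configured minimum."""

    def __init__(self, count: int, min_pixels: int):
        self.count = count
        self.min_pixels = min_pixels
        super().__init__(
            f"largest region has {count} pixels, below the minimum of {min_pixels}"
        )


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the background classifier; defaults match the rig model."""

    min_pixels: int = 5000
    background_value_floor: float = 0.65  # V above this can be background
    closing_size: int = 3
    closing_iterations: int = 2


@dataclass(frozen=True)
class LeafImage:
    """8-bit RGB raster with provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source: str = "<memory>"

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LeafMask:
    mask: np.ndarray  # (H, W) bool
    pixel_count: int


@dataclass(frozen=True)
class ColorFeatures:
    """Per-leaf mean color features in three color spaces.

    R, G, B on the 0-255 scale; H in degrees; S, V, r, g, b fractions;
    L in [0, 100]; a, b signed.  ``n_black`` counts pixels excluded from the
    chromatic-rgb average because their channel sum was zero.
    """

    leaf_id: str
    pixel_count: int
    R: float
    G: float
    B: float
    H: float
    S: float
    V: float
    L: float
    a: float
    b_lab: float
    r: float
    g: float
    b: float
    n_black: int = 0

    def as_dict(self) -> dict:
        return {
            "leaf_id": self.leaf_id, "pixel_count": self.pixel_count,
            "R": self.R, "G": self.G, "B": self.B,
            "H": self.H, "S": self.S, "V": self.V,
            "L": self.L, "a": self.a, "b": self.b_lab,
            "r": self.r, "g": self.g, "b_frac": self.b,
        }


def load_image(path) -> LeafImage:
    """Read a PNG/JPEG as an 8-bit RGB raster (grayscale promoted to 3 channels)."""
    p = Path(path)
    try:
        with Image.open(p) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot read image {p}: {exc}") from exc
    return LeafImage(pixels=arr, source=str(p))


def segment_leaf(image: LeafImage, config: SegmentationConfig | None = None) -> LeafMask:
    """Binary mask of the largest non-background region.

    Deterministic for a fixed image and config.  Raises
    :class:`NoLeafFoundError` when nothing but background is present and
    :class:`MinPixelCountError` when the largest region is too small.
    """
    cfg = config or SegmentationConfig()
    hsv = rgb_to_hsv_array(image.pixels)
    s, v = hsv[..., 1], hsv[..., 2]

    s_vals = s.ravel()
    if float(np.ptp(s_vals)) == 0.0:
        # uniform saturation: fall back to "anything not bright is leaf"
        background = v > cfg.background_value_floor
    else:
        thr = threshold_otsu(s_vals)
        background = (s < thr) & (v > cfg.background_value_floor)
    foreground = ~background

    if not foreground.any():
        raise NoLeafFoundError(f"no foreground pixels found in {image.source}")

    fp = footprint_rectangle((cfg.closing_size, cfg.closing_size))
    cleaned = foreground
    for _ in range(cfg.closing_iterations):
        cleaned = closing(cleaned, fp)
    cleaned = ndimage.binary_fill_holes(cleaned)

    labels, n_labels = ndimage.label(cleaned)
    if n_labels == 0:
        raise NoLeafFoundError(f"no foreground region found in {image.source}")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_labels + 1))
    largest = int(np.argmax(sizes)) + 1
    count = int(sizes[largest - 1])
    if count < cfg.min_pixels:
        raise MinPixelCountError(count, cfg.min_pixels)
    return LeafMask(mask=labels == largest, pixel_count=count)


def extract_mean_features(image: LeafImage, mask: LeafMask, leaf_id: str) -> ColorFeatures:
    """Arithmetic means of the 12 color features over the masked pixels.

    Hue is averaged as an angle (vector mean); chromatic fractions exclude
    black pixels, whose count is carried in ``n_black``.
    """
    if mask.mask.shape != image.pixels.shape[:2]:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image {image.pixels.shape[:2]}"
        )
    px = image.pixels[mask.mask].astype(np.float64)  # (N, 3)
    if px.shape[0] == 0:
        raise ValueError("mask selects no pixels")

    mean_rgb = px.mean(axis=0)
    hsv = rgb_to_hsv_array(px)
    lab = rgb_to_lab_array(px)
    frac, defined = normalize_rgb_array(px)
    n_black = int((~defined).sum())
    if defined.any():
        mean_frac = np.nanmean(frac[defined], axis=0)
    else:
        mean_frac = np.full(3, np.nan)

    return ColorFeatures(
        leaf_id=leaf_id,
        pixel_count=mask.pixel_count,
        R=float(mean_rgb[0]), G=float(mean_rgb[1]), B=float(mean_rgb[2]),
        H=circular_mean_degrees(hsv[:, 0]),
        S=float(hsv[:, 1].mean()), V=float(hsv[:, 2].mean()),
        L=float(lab[:, 0].mean()), a=float(lab[:, 1].mean()),
        b_lab=float(lab[:, 2].mean()),
        r=float(mean_frac[0]), g=float(mean_frac[1]), b=float(mean_frac[2]),
        n_black=n_black,
    )


def features_to_frame(features: list[ColorFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.as_dict() for f in features], columns=FEATURE_COLUMNS)


def write_mask_png(mask: LeafMask, path) -> None:
    """Write the mask as a single-channel PNG with values 0/255."""
    Image.fromarray((mask.mask.astype(np.uint8)) * 255, mode="L").save(path)
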