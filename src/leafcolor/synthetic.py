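"""Synthetic fixtures with known ground truth: leaf-shaped colored blobs on
a near-white canvas, and study-shaped tables linking pigment contents, SPAD
readings and mean color channels.

The image generator rasterizes a (optionally lobed) rotated ellipse,
paints it with a base color plus i.i.d. Gaussian channel noise, and records
the exact rasterized mask and the true painted color, so segmentation and
feature-averaging accuracy can be scored against ground truth.

The tabular generator emulates the statistical structure of a leaf-color
study of green- and anthocyanin-rich vegetables:

* three anthocyanin classes (high/medium/low, default 100/100/120 of
  n = 320) with class-specific pigment ranges;
* SPAD as a power law of chlorophyll content plus noise;
* carotenoids linear in chlorophyll plus noise;
* the G/R channel ratio declining logarithmically in the Anth/Chl ratio,
  with a configurable elbow ("knee");
* mean R, G, B channels driven by SPAD and G/R, with TREx = 2R - G - B an
  exact linear function of the noiseless SPAD signal plus its own noise.

The Anth/Chl covariate is laid out on a deterministic per-class log-spaced
design (randomness enters through the response noise only).  For a
logarithmic trend the chord-extremum elbow over [x1, xn] sits at
x* = (xn - x1)/ln(xn/x1) regardless of the coefficients, so the generator
*solves the upper end of the Anth/Chl range from the configured knee*: the
ground-truth elbow is then exactly the knee parameter.  All generating
functions and parameters are returned alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import polygon

from .imaging import LeafImage

# ---------------------------------------------------------------------------
# leaf images


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """One leaf blob: geometry, paint color, noise and canvas."""

    canvas_height: int = 300
    canvas_width: int = 400
    area: float = 20000.0  # requested blob area in pixels
    aspect: float = 0.55  # minor/major axis ratio
    rotation_deg: float = 0.0
    lobe_amplitude: float = 0.0  # radial modulation fraction, 0 = pure ellipse
    lobe_count: int = 5
    base_color: tuple[int, int, int] = (60, 120, 45)
    channel_noise_sd: float = 0.0
    background_mean: float = 250.0
    background_noise_sd: float = 3.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticLeaf:
    image: LeafImage
    true_mask: np.ndarray  # (H, W) bool, exact rasterized blob
    true_color: tuple[int, int, int]
    spec: SyntheticLeafSpec


def make_leaf_image(spec: SyntheticLeafSpec) -> SyntheticLeaf:
    """Render one synthetic leaf; deterministic for a fixed spec/seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_height, spec.canvas_width

    # semi-axes from requested area: pi*a*b = area, b = aspect*a
    a_major = math.sqrt(spec.area / (math.pi * spec.aspect))
    b_minor = spec.aspect * a_major
    if 2 * a_major > min(h, w):
        raise ValueError(
            f"blob (major diameter {2 * a_major:.0f}px) larger than canvas {h}x{w}"
        )

    theta = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    radial = 1.0 + spec.lobe_amplitude * np.cos(spec.lobe_count * theta)
    ex = a_major * radial * np.cos(theta)
    ey = b_minor * radial * np.sin(theta)
    rot = math.radians(spec.rotation_deg)
    xs = ex * math.cos(rot) - ey * math.sin(rot) + w / 2.0
    ys = ex * math.sin(rot) + ey * math.cos(rot) + h / 2.0

    rr, cc = polygon(ys, xs, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True

    canvas = rng.normal(spec.background_mean, spec.background_noise_sd, size=(h, w, 3))
    paint = np.asarray(spec.base_color, dtype=np.float64)
    if spec.channel_noise_sd > 0:
        noise = rng.normal(0.0, spec.channel_noise_sd, size=(int(mask.sum()), 3))
        canvas[mask] = paint + noise
    else:
        canvas[mask] = paint
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return SyntheticLeaf(
        image=LeafImage(pixels=pixels, source=f"<synthetic seed={spec.seed}>"),
        true_mask=mask,
        true_color=spec.base_color,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# study-shaped tables


def solve_upper_bound_for_knee(x_min: float, knee: float) -> float:
    """Upper end xn of an x-range such that the chord elbow of a logarithmic
    curve over [x_min, xn] falls exactly at the knee.

    Solves (xn - x_min)/ln(xn/x_min) = knee for xn > knee > x_min.
    """
    if not 0 < x_min < knee:
        raise ValueError(f"need 0 < x_min < knee (got x_min={x_min}, knee={knee})")

    def f(xn: float) -> float:
        return (xn - x_min) / math.log(xn / x_min) - knee

    lo = knee * (1.0 + 1e-9)
    hi = knee * 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * knee:
            raise ValueError("knee not attainable from this x_min")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Study-shaped dataset: sizes, class structure, ranges and forward model.

    Default sizes and pigment ranges mirror a six-vegetable study with
    n = 320 leaves in high/medium/low anthocyanin classes.  ``knee`` is the
    ground-truth elbow of the G/R vs Anth/Chl logarithmic relation;
    ``gr_target_r2`` calibrates the G/R noise so the relation's sample R²
    concentrates on the target (None means use ``gr_noise_sd`` directly).
    """

    n: int = 320
    class_proportions: tuple[float, float, float] = (100 / 320, 100 / 320, 120 / 320)
    # per-class pigment ranges (mg/g FW), order HA, MA, LA
    chl_ranges: tuple = ((0.47, 2.1), (0.1, 2.1), (0.06, 2.3))
    anth_ranges: tuple = ((0.07, 3.42), (0.001, 0.33), (0.001, 0.07))
    car_range: tuple[float, float] = (0.03, 0.38)
    # Anth/Chl design
    knee: float = 0.2
    ratio_min: float = 0.005
    # forward model
    spad_scale: float = 40.0  # SPAD = spad_scale * Chl**spad_power + noise
    spad_power: float = 0.55
    spad_noise_sd: float = 3.0
    car_intercept: float = 0.05  # Car = intercept + slope*Chl + noise
    car_slope: float = 0.14
    car_noise_sd: float = 0.03
    gr_slope: float = -0.17  # G/R = gr_slope*ln(ratio) + gr_intercept + noise
    gr_intercept: float = field(default=1.0 + 1.609437912434100 * -0.17)
    gr_noise_sd: float = 0.0
    gr_target_r2: float | None = 0.85
    r_intercept: float = 155.0  # R = r_intercept - r_slope*SPAD_clean + noise
    r_slope: float = 1.6
    r_noise_sd: float = 2.0
    trex_intercept: float = 30.0  # TREx = intercept - slope*SPAD_clean + noise
    trex_slope: float = 1.2
    trex_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions must sum to 1, got {self.class_proportions}"
            )


CLASS_NAMES = ("HA", "MA", "LA")


def _class_sizes(spec: SyntheticStudySpec) -> list[int]:
    raw = [p * spec.n for p in spec.class_proportions]
    sizes = [int(round(v)) for v in raw]
    sizes[-1] = spec.n - sum(sizes[:-1])
    return sizes


def make_study_dataset(spec: SyntheticStudySpec) -> tuple[pd.DataFrame, dict]:
    """Generate the study table and a ground-truth parameter dict.

    Columns: leaf_id, class, Chl, Car, Anth, Anth/Chl, SPAD, R, G, B and the
    derived features G/R, GMR, AGRI, TREx (all consistent with the channel
    columns).  The returned dict records every generating function's
    parameters plus the solved Anth/Chl range and the true elbow.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)

    ratio_max = solve_upper_bound_for_knee(spec.ratio_min, spec.knee)
    # per-class Anth/Chl ranges: LA at the low end, HA reaching the top
    class_ratio_ranges = {
        "HA": (0.05, ratio_max),
        "MA": (0.02, 0.7 * ratio_max),
        "LA": (spec.ratio_min, 0.05),
    }

    rows: list[dict] = []
    for cls, size, chl_rng, anth_rng in zip(
        CLASS_NAMES, sizes, spec.chl_ranges, spec.anth_ranges
    ):
        r_lo, r_hi = class_ratio_ranges[cls]
        # deterministic log-spaced covariate design including both endpoints
        ratios = np.geomspace(r_lo, r_hi, size)
        for k, ratio in enumerate(ratios):
            # chlorophyll drawn so that Anth = ratio * Chl stays in range
            lo = max(chl_rng[0], anth_rng[0] / ratio)
            hi = min(chl_rng[1], anth_rng[1] / ratio)
            if not lo < hi:
                raise ValueError(
                    f"empty Chl range for class {cls} at Anth/Chl={ratio:.4g}"
                )
            chl = float(rng.uniform(lo, hi))
            rows.append({"class": cls, "ratio": ratio, "Chl": chl})

    df = pd.DataFrame(rows)
    n = len(df)
    df.insert(0, "leaf_id", [f"leaf_{i:04d}" for i in range(n)])
    df["Anth"] = df["ratio"] * df["Chl"]
    df["Car"] = np.clip(
        spec.car_intercept + spec.car_slope * df["Chl"]
        + rng.normal(0.0, spec.car_noise_sd, n),
        spec.car_range[0], spec.car_range[1],
    )

    spad_clean = spec.spad_scale * df["Chl"].to_numpy() ** spec.spad_power
    df["SPAD"] = spad_clean + rng.normal(0.0, spec.spad_noise_sd, n)

    ln_ratio = np.log(df["ratio"].to_numpy())
    gr_clean = spec.gr_slope * ln_ratio + spec.gr_intercept
    if spec.gr_target_r2 is not None:
        # noise sd chosen so the expected sample R² equals the target
        sd_signal = float(np.std(gr_clean))
        gr_sd = sd_signal * math.sqrt(1.0 / spec.gr_target_r2 - 1.0)
    else:
        gr_sd = spec.gr_noise_sd
    gr = gr_clean + rng.normal(0.0, gr_sd, n)

    R = spec.r_intercept - spec.r_slope * spad_clean + rng.normal(0.0, spec.r_noise_sd, n)
    G = R * gr
    trex_val = (
        spec.trex_intercept - spec.trex_slope * spad_clean
        + rng.normal(0.0, spec.trex_noise_sd, n)
    )
    B = 2.0 * R - G - trex_val

    clipped = int(((R < 0) | (R > 255) | (G < 0) | (G > 255) | (B < 0) | (B > 255)).sum())
    R, G, B = (np.clip(v, 0.0, 255.0) for v in (R, G, B))

    df["R"], df["G"], df["B"] = R, G, B
    df["G/R"] = df["G"] / df["R"]
    df["GMR"] = df["G"] - df["R"]
    df["AGRI"] = df["GMR"] * df["G/R"]
    df["TREx"] = 2.0 * df["R"] - df["G"] - df["B"]
    df = df.rename(columns={"ratio": "Anth/Chl"})
    df = df[
        ["leaf_id", "class", "Chl", "Car", "Anth", "Anth/Chl", "SPAD",
         "R", "G", "B", "G/R", "GMR", "AGRI", "TREx"]
    ]

    truth = {
        "n": n,
        "class_sizes": dict(zip(CLASS_NAMES, sizes)),
        "ratio_range": (spec.ratio_min, ratio_max),
        "knee": spec.knee,
        "spad_model": {
            "form": "power", "scale": spec.spad_scale, "power": spec.spad_power,
            "noise_sd": spec.spad_noise_sd,
        },
        "car_model": {
            "form": "linear", "intercept": spec.car_intercept,
            "slope": spec.car_slope, "noise_sd": spec.car_noise_sd,
        },
        "gr_model": {
            "form": "logarithmic", "slope": spec.gr_slope,
            "intercept": spec.gr_intercept, "noise_sd": gr_sd,
            "target_r2": spec.gr_target_r2,
        },
        "r_model": {
            "form": "linear_in_spad", "intercept": spec.r_intercept,
            "slope": -spec.r_slope, "noise_sd": spec.r_noise_sd,
        },
        "trex_model": {
            "form": "linear_in_spad", "intercept": spec.trex_intercept,
            "slope": -spec.trex_slope, "noise_sd": spec.trex_noise_sd,
        },
        "n_channel_clipped": clipped,
        "seed": spec.seed,
    }
    return df, truth
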