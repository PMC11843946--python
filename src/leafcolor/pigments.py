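"""Spectrophotometric pigment quantification.

Chlorophyll and carotenoid contents come from 80% acetone-extract
absorbances through Lichtenthaler-type equations::

    Chl (mg/g FW) = (18.71 A647 + 7.15 A663) * Vol / (1000 * FW)
    Car (mg/g FW) = (1000 A470 - 1822.85 A647 + 411.31 A663) * Vol
                    / (198 * 1000 * FW)

Anthocyanin content uses the Mancinelli approach: the acidified-methanol
absorbance A530 is pheophytin-corrected by subtracting 0.25 * A657, and the
corrected absorbance is converted to a concentration against a
cyanidin-3-O-glucoside standard curve, then scaled by extract volume over
fresh weight.

Units: FW in grams, Vol in millilitres (the 1000 divisor converts the
absorbance-derived microgram/ml scale to mg/g), contents in mg per g FW.
Negative computed contents are physically impossible but can arise from
noisy absorbances; they are *flagged*, never clipped, to keep batch
pipelines auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PHEOPHYTIN_CORRECTION = 0.25  # multiplier on A657 subtracted from A530


@dataclass(frozen=True)
class PigmentSample:
    """Absorbances plus fresh weight (g) and extract volume (ml) for one leaf."""

    sample_id: str
    FW: float
    Vol: float
    A470: float = 0.0
    A647: float = 0.0
    A663: float = 0.0
    A530: float = 0.0
    A657: float = 0.0

    def __post_init__(self) -> None:
        if not self.FW > 0:
            raise ValueError(f"{self.sample_id}: FW must be > 0, got {self.FW}")
        if not self.Vol > 0:
            raise ValueError(f"{self.sample_id}: Vol must be > 0, got {self.Vol}")
        for name in ("A470", "A647", "A663", "A530", "A657"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{self.sample_id}: {name}={v} must be finite and >= 0")


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"standard-curve slope must be > 0, got {self.slope}")
        if self.n_points < 2:
            raise ValueError("standard curve needs at least 2 points")


@dataclass(frozen=True)
class PigmentResult:
    """Contents in mg/g FW, pigment ratios, and quality flags."""

    sample_id: str
    Chl: float
    Car: float
    Anth: float
    anth_chl_ratio: float
    car_chl_ratio: float
    ratios_defined: bool = True
    negative_flags: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class SPADRecord:
    """Three SPAD-meter readings per leaf and their arithmetic mean."""

    leaf_id: str
    readings: tuple[float, float, float]
    mean_spad: float = math.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_spad", float(np.mean(self.readings)))


def _check_vol_fw(Vol: float, FW: float) -> None:
    if not (Vol > 0 and FW > 0):
        raise ValueError(f"Vol and FW must be > 0 (got Vol={Vol}, FW={FW})")


def chlorophyll_content(A647: float, A663: float, Vol: float, FW: float) -> float:
    """Total chlorophyll in mg per g fresh weight."""
    _check_vol_fw(Vol, FW)
    return (18.71 * A647 + 7.15 * A663) * Vol / (1000.0 * FW)


def carotenoid_content(
    A470: float, A647: float, A663: float, Vol: float, FW: float
) -> float:
    """Total carotenoids in mg per g fresh weight."""
    _check_vol_fw(Vol, FW)
    return (1000.0 * A470 - 1822.85 * A647 + 411.31 * A663) * Vol / (198.0 * 1000.0 * FW)


def anthocyanin_corrected_absorbance(A530: float, A657: float) -> float:
    """Pheophytin-corrected anthocyanin absorbance, A530 - 0.25 * A657.

    May be negative for noisy inputs; downstream code carries a flag.
    """
    return A530 - PHEOPHYTIN_CORRECTION * A657


def calibrate_standard_curve(
    points: list[tuple[float, float]], *, through_origin: bool = False
) -> StandardCurve:
    """Fit the cyanidin-3-O-glucoside calibration line by least squares.

    ``points`` are (concentration in mg/ml, corrected absorbance) pairs.
    By default the intercept is free; ``through_origin=True`` forces the
    line through (0, 0).
    """
    if len(points) < 2:
        raise ValueError("standard curve needs at least 2 points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    absb = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("standard-curve concentrations have zero variance")
    if through_origin:
        slope = float(conc @ absb / (conc @ conc))
        intercept = 0.0
        fitted = slope * conc
        ss_res = float(((absb - fitted) ** 2).sum())
        ss_tot = float(((absb - absb.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    else:
        res = stats.linregress(conc, absb)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return StandardCurve(slope=slope, intercept=intercept, r_squared=r2, n_points=len(points))


def anthocyanin_content(
    A_corr: float, curve: StandardCurve, Vol: float, FW: float
) -> float:
    """Anthocyanin in mg per g FW from a corrected absorbance.

    Concentration (mg/ml) is read off the inverted standard curve and scaled
    by extract volume (ml) over fresh weight (g).
    """
    _check_vol_fw(Vol, FW)
    concentration = (A_corr - curve.intercept) / curve.slope
    return concentration * Vol / FW


def pigment_ratios(Anth: float, Car: float, Chl: float) -> tuple[float, float, bool]:
    """(Anth/Chl, Car/Chl, defined) — ratios are undefined when Chl = 0."""
    if Chl == 0:
        return math.nan, math.nan, False
    return Anth / Chl, Car / Chl, True


def analyze_sample(sample: PigmentSample, curve: StandardCurve) -> PigmentResult:
    """Full pigment workup for one sample: contents, ratios, and flags."""
    chl = chlorophyll_content(sample.A647, sample.A663, sample.Vol, sample.FW)
    car = carotenoid_content(sample.A470, sample.A647, sample.A663, sample.Vol, sample.FW)
    a_corr = anthocyanin_corrected_absorbance(sample.A530, sample.A657)
    anth = anthocyanin_content(a_corr, curve, sample.Vol, sample.FW)
    anth_chl, car_chl, defined = pigment_ratios(anth, car, chl)
    flags = tuple(
        name for name, v in (("Chl", chl), ("Car", car), ("Anth", anth)) if v < 0
    )
    return PigmentResult(
        sample_id=sample.sample_id,
        Chl=chl,
        Car=car,
        Anth=anth,
        anth_chl_ratio=anth_chl,
        car_chl_ratio=car_chl,
        ratios_defined=defined,
        negative_flags=flags,
    )


# ---------------------------------------------------------------------------
# CSV plumbing

SAMPLE_COLUMNS = ["sample_id", "FW", "Vol", "A470", "A647", "A663", "A530", "A657"]
RESULT_COLUMNS = ["sample_id", "Chl", "Car", "Anth", "Anth/Chl", "Car/Chl", "flags"]


def read_samples_csv(path) -> list[PigmentSample]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pigment CSV {path} missing columns: {missing}")
    return [
        PigmentSample(
            sample_id=str(row.sample_id), FW=row.FW, Vol=row.Vol,
            A470=row.A470, A647=row.A647, A663=row.A663,
            A530=row.A530, A657=row.A657,
        )
        for row in df.itertuples()
    ]


def read_standard_curve_csv(path, **kwargs) -> StandardCurve:
    df = pd.read_csv(path, comment="#")
    for col in ("concentration", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"standard-curve CSV {path} missing column {col!r}")
    pts = list(zip(df["concentration"].astype(float), df["absorbance"].astype(float)))
    return calibrate_standard_curve(pts, **kwargs)


def results_to_frame(results: list[PigmentResult]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id, "Chl": r.Chl, "Car": r.Car, "Anth": r.Anth,
            "Anth/Chl": r.anth_chl_ratio, "Car/Chl": r.car_chl_ratio,
            "flags": ";".join(
                (["ratios_undefined"] if not r.ratios_defined else [])
                + [f"negative_{n}" for n in r.negative_flags]
            ),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
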