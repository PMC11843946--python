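"""Trendline fitting, best-model selection by R², and elbow location via
the Extremum Distance Estimator (EDE).

Five curve families are supported, matching spreadsheet trendlines:

========== ======================= ==========================================
family     model                   fitting space
========== ======================= ==========================================
linear     y = m x + c             direct least squares
quadratic  y = a x² + b x + c      direct least squares
logarithmic y = a ln(x) + b        least squares in ln(x)
exponential y = a e^(b x)          least squares of ln(y) on x
power      y = a x^b               least squares of ln(y) on ln(x)
========== ======================= ==========================================

For the exponential and power families the reported R² is computed in the
space where residuals were minimized (log space), which is the spreadsheet
trendline convention; ``FitResult.fit_space`` records this.  An optional
nonlinear refinement (``refine=True``) polishes the linearized estimate with
least squares in the original space.

The EDE draws the chord from the first to the last data point and examines
the signed vertical deviations d_i = y_i - chord(x_i):

* ``ede_sigmoid`` — midpoint of the abscissas of min(d) and max(d); suited
  to S-shaped curves whose deviations change sign.
* ``ede_knee`` — abscissa of max |d|; suited to one-signed convex/concave
  curves (the "elbow" of a saturating trend).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "quadratic", "exponential", "logarithmic", "power")

#: number of evaluation points when an elbow is located on a fitted curve
ELBOW_GRID_SIZE = 512

_N_COEF = {"linear": 2, "quadratic": 3, "exponential": 2, "logarithmic": 2, "power": 2}


@dataclass(frozen=True)
class FitResult:
    family: str
    coefficients: dict[str, float]
    r_squared: float
    n: int
    fit_space: str = "original"  # or "log-transformed"
    degenerate: bool = False  # constant-y input; R² reported as 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c["m"] * x + c["c"]
        if self.family == "quadratic":
            return c["a"] * x**2 + c["b"] * x + c["c"]
        if self.family == "logarithmic":
            return c["a"] * np.log(x) + c["b"]
        if self.family == "exponential":
            return c["a"] * np.exp(c["b"] * x)
        if self.family == "power":
            return c["a"] * x ** c["b"]
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class InflectionEstimate:
    """EDE elbow: abscissa plus the chord-extremum indices that support it."""

    x_star: float
    method: str
    left_index: int
    right_index: int
    n: int


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Constant observations (SS_tot = 0) make R² undefined; by policy 0.0 is
    returned so that degenerate relations sort below any informative fit.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0
    ss_res = float(((y - y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _check_domain(x: np.ndarray, y: np.ndarray, family: str) -> None:
    if family in ("logarithmic", "power"):
        bad = np.flatnonzero(x <= 0)
        if bad.size:
            raise ValueError(
                f"{family} fit needs x > 0; offending indices: {bad.tolist()[:20]}"
            )
    if family in ("exponential", "power"):
        bad = np.flatnonzero(y <= 0)
        if bad.size:
            raise ValueError(
                f"{family} fit needs y > 0; offending indices: {bad.tolist()[:20]}"
            )


def fit_curve(x, y, family: str, *, refine: bool = False) -> FitResult:
    """Least-squares fit of one trendline family.

    Exponential and power models are linearized through logs (the
    spreadsheet convention); ``refine=True`` follows with nonlinear least
    squares in the original space, recorded in ``fit_space``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < _N_COEF[family] + 1:
        raise ValueError(f"{family} fit needs at least {_N_COEF[family] + 1} points")
    _check_domain(x, y, family)

    degenerate = float(np.ptp(y)) == 0.0

    if family == "linear":
        m, c = np.polyfit(x, y, 1)
        coef = {"m": float(m), "c": float(c)}
        space = "original"
    elif family == "quadratic":
        a, b, c = np.polyfit(x, y, 2)
        coef = {"a": float(a), "b": float(b), "c": float(c)}
        space = "original"
    elif family == "logarithmic":
        a, b = np.polyfit(np.log(x), y, 1)
        coef = {"a": float(a), "b": float(b)}
        space = "original"
    elif family == "exponential":
        b, ln_a = np.polyfit(x, np.log(y), 1)
        coef = {"a": float(np.exp(ln_a)), "b": float(b)}
        space = "log-transformed"
    else:  # power
        b, ln_a = np.polyfit(np.log(x), np.log(y), 1)
        coef = {"a": float(np.exp(ln_a)), "b": float(b)}
        space = "log-transformed"

    if refine and family in ("exponential", "power"):
        def model(xv, a, b):
            return a * np.exp(b * xv) if family == "exponential" else a * xv**b

        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=[coef["a"], coef["b"]], maxfev=10000
            )
            coef = {"a": float(popt[0]), "b": float(popt[1])}
            space = "original"
        except RuntimeError:  # keep the linearized estimate
            logger.warning("nonlinear refinement failed for %s fit; keeping linearized", family)

    result = FitResult(family, coef, math.nan, n, fit_space=space, degenerate=degenerate)
    if degenerate:
        r2 = 0.0
    elif space == "log-transformed":
        # R² in the space where residuals were minimized
        ln_yhat = np.log(result.predict(x))
        r2 = r_squared(np.log(y), ln_yhat)
    else:
        r2 = r_squared(y, result.predict(x))
    return FitResult(family, coef, r2, n, fit_space=space, degenerate=degenerate)


def best_fit(x, y, families=FAMILIES, *, refine: bool = False) -> FitResult:
    """Fit every admissible family and return the one with maximal R².

    Ties are broken toward fewer coefficients (the simpler model); families
    whose domain requirements the data violate are skipped with a log note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fits: list[FitResult] = []
    for family in families:
        try:
            fits.append(fit_curve(x, y, family, refine=refine))
        except ValueError as exc:
            logger.info("skipping %s family: %s", family, exc)
    if not fits:
        raise ValueError("no admissible curve family for these data")
    # ties (to within numerical noise) break toward fewer coefficients
    best_r2 = max(f.r_squared for f in fits)
    tied = [f for f in fits if f.r_squared >= best_r2 - 1e-9]
    return min(tied, key=lambda f: (_N_COEF[f.family], -f.r_squared))


def ede_inflection(x, y, method: str = "ede_knee") -> InflectionEstimate:
    """Locate an elbow/inflection by the Extremum Distance Estimator.

    The chord runs from (x_1, y_1) to (x_n, y_n); d_i are the signed
    vertical deviations of the data from the chord.  ``ede_sigmoid`` returns
    the midpoint of the abscissas of min(d) and max(d); ``ede_knee`` returns
    the abscissa of max |d|.
    """
    if method not in ("ede_sigmoid", "ede_knee"):
        raise ValueError(f"unknown EDE method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("EDE needs at least 4 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")

    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    chord = y[0] + slope * (x - x[0])
    d = y - chord

    if method == "ede_sigmoid":
        i_min, i_max = int(np.argmin(d)), int(np.argmax(d))
        left, right = sorted((i_min, i_max))
        x_star = 0.5 * (x[i_min] + x[i_max])
    else:
        i = int(np.argmax(np.abs(d)))
        left = right = i
        x_star = float(x[i])
    return InflectionEstimate(float(x_star), method, left, right, n)


@dataclass(frozen=True)
class RelationAnalysis:
    fit: FitResult
    elbow: InflectionEstimate | None
    n_dropped: int


def analyze_relation(
    x,
    y,
    *,
    elbow: bool = False,
    elbow_method: str = "ede_knee",
    families=FAMILIES,
    refine: bool = False,
) -> RelationAnalysis:
    """Best trendline for an x-y relation, optionally with its elbow.

    Non-finite entries are dropped pairwise (count reported).  When an elbow
    is requested it is located on the *fitted* curve evaluated on a dense
    uniform grid (:data:`ELBOW_GRID_SIZE` points) over the observed x-range,
    not on the raw scatter.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int(x.size - keep.sum())
    x, y = x[keep], y[keep]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size < 4:
        raise ValueError(f"need at least 4 retained pairs, have {x.size}")

    fit = best_fit(x, y, families=families, refine=refine)

    estimate = None
    if elbow and not fit.degenerate:
        grid = np.linspace(x[0], x[-1], ELBOW_GRID_SIZE)
        estimate = ede_inflection(grid, fit.predict(grid), method=elbow_method)
    return RelationAnalysis(fit=fit, elbow=estimate, n_dropped=n_dropped)
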