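"""Trendline fitting, model selection, and EDE elbow detection."""

import numpy as np
import pytest

from leafcolor.curvefit import (
    ELBOW_GRID_SIZE,
    analyze_relation,
    best_fit,
    ede_inflection,
    fit_curve,
    r_squared,
)


def brute_force_ede(x, y, method):
    """Explicit argmin/argmax chord-deviation oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    d = y - (y[0] + slope * (x - x[0]))
    if method == "ede_sigmoid":
        return 0.5 * (x[np.argmin(d)] + x[np.argmax(d)])
    return x[np.argmax(np.abs(d))]


# --- r_squared ------------------------------------------------------------

def test_r_squared_values():
    y = np.array([1.0, 2.0, 3.0, 5.0])
    assert r_squared(y, y) == 1.0
    assert r_squared(y, np.full(4, y.mean())) == 0.0
    assert r_squared(y, np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1 - 1 / 8.75)


def test_r_squared_contracts():
    with pytest.raises(ValueError):
        r_squared(np.arange(3.0), np.arange(4.0))
    assert r_squared(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.1, 1.9])) == 0.0


# --- fit_curve ------------------------------------------------------------

GENERATORS = {
    "linear": ({"m": 2.0, "c": 1.0}, lambda x, c: c["m"] * x + c["c"]),
    "quadratic": ({"a": 0.5, "b": -2.0, "c": 3.0},
                  lambda x, c: c["a"] * x**2 + c["b"] * x + c["c"]),
    "logarithmic": ({"a": 3.0, "b": 1.0}, lambda x, c: c["a"] * np.log(x) + c["b"]),
    "exponential": ({"a": 1.5, "b": 0.3}, lambda x, c: c["a"] * np.exp(c["b"] * x)),
    "power": ({"a": 2.0, "b": 1.5}, lambda x, c: c["a"] * x ** c["b"]),
}


@pytest.mark.parametrize("family", list(GENERATORS))
def test_noiseless_parameter_recovery(family):
    true, model = GENERATORS[family]
    x = np.linspace(1.0, 10.0, 40)
    y = model(x, true)
    fit = fit_curve(x, y, family)
    for name, val in true.items():
        assert fit.coefficients[name] == pytest.approx(val, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
    assert fit.n == 40


def test_fit_spaces_recorded():
    x = np.linspace(1, 5, 20)
    assert fit_curve(x, 2 * x + 1, "linear").fit_space == "original"
    assert fit_curve(x, 2 * np.exp(0.1 * x), "exponential").fit_space == "log-transformed"
    refined = fit_curve(x, 2 * np.exp(0.1 * x), "exponential", refine=True)
    assert refined.fit_space == "original"
    assert refined.coefficients["a"] == pytest.approx(2.0, rel=1e-6)


def test_domain_violations_list_offending_indices():
    x = np.array([-1.0, 1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match=r"\[0\]"):
        fit_curve(x, np.ones(4), "logarithmic")
    y = np.array([1.0, -2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match=r"\[1\]"):
        fit_curve(np.arange(1.0, 5.0), y, "exponential")


# --- best_fit -------------------------------------------------------------

def test_exact_linear_prefers_fewer_coefficients():
    x = np.linspace(0, 10, 25)
    fit = best_fit(x, 2 * x + 1, families=("linear", "quadratic"))
    assert fit.family == "linear"


def test_exponential_data_selects_exponential():
    x = np.linspace(0.5, 5, 30)
    fit = best_fit(x, 1.5 * np.exp(0.4 * x))
    assert fit.family == "exponential"
    assert fit.coefficients["a"] == pytest.approx(1.5, rel=1e-6)


def test_constant_y_returns_flagged_linear():
    x = np.linspace(1, 10, 10)
    fit = best_fit(x, np.full(10, 3.0))
    assert fit.family == "linear"
    assert fit.degenerate
    assert fit.r_squared == 0.0
    assert fit.coefficients["m"] == pytest.approx(0.0, abs=1e-12)


def test_inadmissible_families_skipped():
    x = np.linspace(-3, 3, 15)  # nonpositive x excludes log/power
    fit = best_fit(x, 2 * x + 1)
    assert fit.family == "linear"
    with pytest.raises(ValueError):
        best_fit(x, -np.abs(x) - 1, families=("exponential", "power"))


# --- ede_inflection -------------------------------------------------------

def test_tanh_midpoint_recovered():
    x = np.linspace(-3, 3, 61)
    est = ede_inflection(x, np.tanh(x), method="ede_sigmoid")
    assert abs(est.x_star) <= (x[1] - x[0])


def test_logistic_midpoint_within_one_grid_step():
    x = np.linspace(-4, 6, 101)
    y = 1 / (1 + np.exp(-(x - 1)))
    est = ede_inflection(x, y, method="ede_sigmoid")
    assert abs(est.x_star - 1.0) <= (x[1] - x[0])


def test_piecewise_linear_knee_exact():
    x = np.linspace(0, 6, 61)
    y = np.where(x < 2, 5 - 2 * x, 1 - 0.05 * (x - 2))  # convex knee at x=2
    est = ede_inflection(x, y, method="ede_knee")
    assert est.x_star == pytest.approx(2.0)


@pytest.mark.parametrize("method", ["ede_sigmoid", "ede_knee"])
def test_matches_brute_force_oracle(method):
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = int(rng.integers(5, 80))
        x = np.sort(rng.uniform(0, 10, n))
        x += np.arange(n) * 1e-9  # guarantee strict monotonicity
        y = rng.normal(size=n).cumsum()
        est = ede_inflection(x, y, method=method)
        assert est.x_star == pytest.approx(brute_force_ede(x, y, method))


def test_ede_affine_invariance():
    x = np.linspace(-4, 6, 101)
    y = 1 / (1 + np.exp(-(x - 1)))
    base = ede_inflection(x, y, method="ede_sigmoid").x_star
    scaled_y = ede_inflection(x, 7 * y - 3, method="ede_sigmoid").x_star
    assert scaled_y == pytest.approx(base)
    shifted = ede_inflection(2 * x + 5, y, method="ede_sigmoid").x_star
    assert shifted == pytest.approx(2 * base + 5)


def test_ede_input_contracts():
    with pytest.raises(ValueError):
        ede_inflection([1, 2, 2, 3], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        ede_inflection([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        ede_inflection([1, 2, 3, 4], [1, 2, 3, 4], method="nope")


# --- analyze_relation -----------------------------------------------------

def test_logarithmic_relation_with_elbow():
    x = np.geomspace(0.005, 1.08, 200)
    y = -0.17 * np.log(x) + 0.7264
    res = analyze_relation(x, y, elbow=True)
    assert res.fit.family == "logarithmic"
    assert res.fit.r_squared == pytest.approx(1.0, abs=1e-9)
    # elbow of a log curve over [x1,xn] sits at (xn-x1)/ln(xn/x1)
    expected = (1.08 - 0.005) / np.log(1.08 / 0.005)
    grid_step = (1.08 - 0.005) / (ELBOW_GRID_SIZE - 1)
    assert abs(res.elbow.x_star - expected) <= grid_step


def test_constant_y_has_no_elbow():
    res = analyze_relation(np.arange(1.0, 11.0), np.full(10, 2.0), elbow=True)
    assert res.fit.degenerate
    assert res.fit.r_squared == 0.0
    assert res.elbow is None


def test_pairwise_deletion_bookkeeping():
    x = np.linspace(1, 10, 30)
    y = 2 * x + 1
    y[::10] = np.nan  # 3 undefined entries
    res = analyze_relation(x, y)
    assert res.n_dropped == 3
    assert res.fit.n == 27


def test_too_few_retained_pairs():
    with pytest.raises(ValueError):
        analyze_relation([1, 2, 3, np.nan], [1, 2, np.nan, 4])
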