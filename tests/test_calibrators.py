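import numpy as np
import pytest
from scipy.optimize import lsq_linear

from thermocal import CalibratorSpec, estimate_error_variance_ratio, fit_calibrator
from thermocal.calibrators import (
    FitError,
    deming_slope_intercept,
    fit_deming,
    fit_isotonic,
    fit_loess,
    fit_monotone_boost,
    fit_polynomial_huber,
    fit_quantile_boost,
    fit_spline_huber,
    fit_tree_ensemble,
    fit_weighted_spline,
    natural_cubic_basis,
)


def brute_force_isotonic(y, w=None):
    """Monotone least squares via bounded LS on cumulative increments.

    yhat = A @ theta with A lower-triangular ones; theta_0 free, rest >= 0.
    Independent of the pool-adjacent-violators implementation under test.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    A = np.tril(np.ones((n, n)))
    sw = np.sqrt(w)
    lb = np.full(n, 0.0)
    lb[0] = -np.inf
    res = lsq_linear(A * sw[:, None], y * sw, bounds=(lb, np.full(n, np.inf)),
                     tol=1e-14)
    return A @ res.x


# --- isotonic / PAVA ---------------------------------------------------------


def test_pava_matches_brute_force_battery():
    """PAVA equals bounded-least-squares monotone fits on 1000 random cases."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = rng.integers(2, 7)
        x = np.sort(rng.uniform(0, 10, n))
        # strictly increasing x so fitted values are unambiguous
        x += np.arange(n) * 1e-3
        y = rng.normal(0, 2, n)
        fitted = fit_isotonic(x, y).predict(x)
        expected = brute_force_isotonic(y)
        np.testing.assert_allclose(fitted, expected, atol=1e-6)


def test_pava_weighted_hand_case():
    # x=[1,2,3], y=[1,3,2] -> [1, 2.5, 2.5]
    fitted = fit_isotonic([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]).predict([1.0, 2.0, 3.0])
    np.testing.assert_allclose(fitted, [1.0, 2.5, 2.5])


def test_isotonic_identity_and_total_pooling():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y_up = np.array([1.0, 1.5, 2.0, 5.0])
    np.testing.assert_allclose(fit_isotonic(x, y_up).predict(x), y_up)
    y_down = y_up[::-1]
    np.testing.assert_allclose(fit_isotonic(x, y_down).predict(x),
                               np.full(4, y_down.mean()))


def test_isotonic_boundary_extension():
    fc = fit_isotonic([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
    np.testing.assert_allclose(fc.predict([-5.0, 100.0]), [10.0, 30.0])
    assert list(fc.extrapolation_mask([0.0, 2.0, 9.0])) == [True, False, True]


# --- Deming ------------------------------------------------------------------


def test_deming_exact_on_collinear_points():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = 2.0 * x + 1.0
    for delta in (0.01, 1.0, 100.0):
        slope, intercept = deming_slope_intercept(x, y, delta)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)


def test_deming_limits_match_ols_and_inverse_regression():
    rng = np.random.default_rng(1)
    x = rng.uniform(30, 38, 200)
    y = 1.2 * x - 5 + rng.normal(0, 0.7, 200)
    ols = np.polyfit(x, y, 1)[0]
    inv = 1.0 / np.polyfit(y, x, 1)[0]
    slope_inf, _ = deming_slope_intercept(x, y, 1e6)
    slope_zero, _ = deming_slope_intercept(x, y, 1e-6)
    assert slope_inf == pytest.approx(ols, rel=1e-4)
    assert slope_zero == pytest.approx(inv, rel=1e-4)


def test_deming_symmetry_at_unit_delta():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 300)
    y = x + rng.normal(0, 1, 300)
    slope_xy, _ = deming_slope_intercept(x, y, 1.0)
    slope_yx, _ = deming_slope_intercept(y, x, 1.0)
    assert slope_xy * slope_yx == pytest.approx(1.0, rel=1e-9)


def test_deming_corrects_attenuation_where_ols_is_biased():
    """Errors in x shrink the OLS slope; Deming recovers the true slope."""
    rng = np.random.default_rng(3)
    mu = rng.normal(35, 1.0, 4000)
    x = mu + rng.normal(0, 0.34, 4000)
    y = mu + rng.normal(0, 0.03, 4000)
    expected_attenuation = 1.0 / (1 + 0.34**2)
    ols = np.polyfit(x, y, 1)[0]
    assert ols == pytest.approx(expected_attenuation, abs=0.03)
    slope, _ = deming_slope_intercept(x, y, (0.03 / 0.34) ** 2)
    assert slope == pytest.approx(1.0, abs=0.03)


def test_deming_centroid_property_and_zero_covariance_error():
    rng = np.random.default_rng(4)
    x = rng.uniform(30, 38, 50)
    y = x + rng.normal(0, 0.5, 50)
    fc = fit_deming(x, y, delta=1.0)
    assert fc.predict([x.mean()])[0] == pytest.approx(y.mean())
    with pytest.raises(FitError, match="covariance"):
        deming_slope_intercept([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], 1.0)


def test_error_variance_ratio_arithmetic(study_table):
    import pandas as pd

    rows = []
    for pid in ("A", "B"):
        for device, sd in (("test", 0.2), ("reference", 0.1)):
            for i, v in enumerate([35.0 - sd, 35.0 + sd], start=1):
                rows.append({"participant_id": pid, "round": "R1", "device": device,
                             "replicate": i, "temperature_c": v})
    toy = pd.DataFrame(rows)
    # per-cell variances are (2 sd)^2/2 = 2 sd^2; ratio = 0.1^2/0.2^2
    assert estimate_error_variance_ratio(toy) == pytest.approx(0.25)
    # default study: ratio near mean(ref variances)/mean(test variances)
    want = np.mean([0.030**2, 0.093**2]) / np.mean([0.340**2, 0.300**2])
    assert estimate_error_variance_ratio(study_table) == pytest.approx(want, rel=0.5)


# --- polynomial + Huber ------------------------------------------------------


def test_polynomial_huber_recovers_exact_line():
    x = np.linspace(0, 10, 40)
    y = 2.0 * x + 1.0
    fc = fit_polynomial_huber(x, y, degree=2, epsilon=1.35, alpha=0.0)
    coefs = fc._point.coefficients
    np.testing.assert_allclose(coefs, [1.0, 2.0, 0.0], atol=1e-6)


def test_polynomial_huber_resists_gross_outlier():
    rng = np.random.default_rng(5)
    x = np.linspace(30, 38, 50)
    y = x + rng.normal(0, 0.1, 50)
    y_out = y.copy()
    y_out[48] += 20.0  # high-leverage gross outlier near the right edge
    clean = np.polyfit(x, y, 1)[0]
    huber = fit_polynomial_huber(x, y_out, degree=1, epsilon=1.35, alpha=0.0)
    hslope = (huber.predict([38.0]) - huber.predict([30.0]))[0] / 8.0
    ols = np.polyfit(x, y_out, 1)[0]
    assert abs(hslope - clean) < 0.05 * abs(clean)
    assert abs(ols - clean) > 3 * abs(hslope - clean)


# --- splines -----------------------------------------------------------------


def test_natural_spline_basis_contains_linear_functions():
    x = np.linspace(0, 1, 60)
    knots = np.quantile(x, np.linspace(0, 1, 6))
    B = natural_cubic_basis(x, knots)
    y = 3.0 * x - 2.0
    coefs, *_ = np.linalg.lstsq(B, y, rcond=None)
    np.testing.assert_allclose(B @ coefs, y, atol=1e-10)


def test_spline_huber_reproduces_line_and_resists_outlier():
    rng = np.random.default_rng(6)
    x = rng.uniform(30, 38, 120)
    y = 0.9 * x + 2.0
    fc = fit_spline_huber(x, y, n_knots=6, epsilon=1.35)
    np.testing.assert_allclose(fc.predict(x), y, atol=1e-8)

    y_noisy = y + rng.normal(0, 0.1, 120)
    y_out = y_noisy.copy()
    y_out[0] += 15.0
    clean = fit_spline_huber(x, y_noisy, 6, 1.35).predict([x[0]])[0]
    robust = fit_spline_huber(x, y_out, 6, 1.35).predict([x[0]])[0]
    assert abs(robust - clean) < 0.05 * abs(clean - 30.0) + 0.1


def test_spline_huber_linear_extrapolation_is_natural():
    x = np.linspace(30, 38, 100)
    y = 1.1 * x - 3.0
    fc = fit_spline_huber(x, y, n_knots=5, epsilon=1.35)
    # natural splines are linear beyond the boundary knots
    left = fc.predict([25.0, 26.0])
    assert (left[1] - left[0]) == pytest.approx(1.1, abs=1e-6)


def test_weighted_spline_matches_unweighted_when_homoscedastic():
    rng = np.random.default_rng(7)
    x = rng.uniform(30, 38, 400)
    y = x + rng.normal(0, 0.3, 400)
    weighted = fit_weighted_spline(x, y, n_knots=6, n_bins=10)
    unweighted = fit_spline_huber(x, y, n_knots=6, epsilon=100.0)  # ~plain LS
    grid = np.linspace(30.5, 37.5, 50)
    assert np.max(np.abs(weighted.predict(grid) - unweighted.predict(grid))) < 0.15


def test_weighted_spline_downweights_noisy_regime():
    rng = np.random.default_rng(8)
    x = np.concatenate([rng.uniform(30, 34, 200), rng.uniform(34, 38, 200)])
    noise = np.where(x < 34, 0.1, 1.0)
    y = x + rng.normal(0, 1, 400) * noise
    fc = fit_weighted_spline(x, y, n_knots=6, n_bins=10)
    w = fc.bin_weights
    ratio = np.median(w[x < 33.5]) / np.median(w[x > 34.5])
    assert ratio > 20  # ~(1.0/0.1)^2 = 100 up to binning noise


def test_weighted_spline_noiseless_monotone_interpolates():
    x = np.linspace(30, 38, 50)
    y = np.sort(np.sqrt(x))
    fc = fit_weighted_spline(x, y, n_knots=6, n_bins=5)
    # variance floor engages; fit limited only by spline approximation error
    np.testing.assert_allclose(fc.predict(x), y, atol=1e-3)


# --- LOESS -------------------------------------------------------------------


def test_loess_constant_and_global_ols_limits():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 10, 60)
    const = fit_loess(x, np.full(60, 5.0), frac=0.5, robust_iters=0)
    np.testing.assert_allclose(const.predict([1.0, 5.0, 9.0]), 5.0, atol=1e-9)

    y = 2.0 * x - 1.0  # exact line: any local fit reproduces it
    fc = fit_loess(x, y, frac=1.0, robust_iters=0)
    np.testing.assert_allclose(fc.predict(x), y, atol=1e-8)


def test_loess_tracks_local_structure():
    rng = np.random.default_rng(10)
    x = np.sort(rng.uniform(0, 2 * np.pi, 300))
    y = np.sin(x) + rng.normal(0, 0.05, 300)
    fc = fit_loess(x, y, frac=0.25, robust_iters=1)
    grid = np.linspace(0.5, 2 * np.pi - 0.5, 30)
    assert np.max(np.abs(fc.predict(grid) - np.sin(grid))) < 0.1


def test_loess_degenerate_neighborhood_errors():
    x = np.array([1.0, 1.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(FitError, match="degenerate neighborhood"):
        fit_loess(x, y, frac=0.6, robust_iters=0).predict([1.0])


# --- boosted quantiles -------------------------------------------------------


def test_quantile_boost_median_tracks_identity(linear_xy):
    x, y = linear_xy
    fc = fit_quantile_boost(x, y, n_estimators=200)
    grid = np.linspace(31, 37, 50)
    assert np.max(np.abs(fc.predict(grid) - grid)) < 0.5
    lo, mid, hi = fc.predict_quantiles(x)
    assert np.all(lo <= mid) and np.all(mid <= hi)
    assert fc.interval_source == "quantile_model"


def test_quantile_boost_rejects_bad_quantiles_and_small_n(linear_xy):
    x, y = linear_xy
    with pytest.raises(ValueError):
        fit_quantile_boost(x, y, quantiles=(0.0, 0.5, 1.0))
    with pytest.raises(FitError):
        fit_quantile_boost(x[:10], y[:10])


def test_monotone_boost_hard_monotonicity(linear_xy):
    x, y = linear_xy
    fc = fit_monotone_boost(x, y, n_estimators=150)
    grid = np.linspace(28, 40, 500)
    pred = fc.predict(grid)
    assert np.all(np.diff(pred) >= 0)
    lo, mid, hi = fc.predict_quantiles(grid)
    assert np.all(lo <= mid) and np.all(mid <= hi)


def test_monotone_boost_near_interpolates_clean_monotone_data():
    x = np.linspace(30, 38, 200)
    y = x.copy()
    fc = fit_monotone_boost(x, y, n_estimators=300)
    assert np.max(np.abs(fc.predict(x) - y)) < 0.3


# --- tree ensembles ----------------------------------------------------------


@pytest.mark.parametrize("kind", ["random_forest", "extra_trees"])
def test_tree_ensembles_fit_constant_and_dense_grid(kind):
    x = np.linspace(30, 38, 100)
    const = fit_tree_ensemble(x, np.full(100, 36.5), kind=kind)
    np.testing.assert_allclose(const.predict([31.0, 35.0]), 36.5)
    fc = fit_tree_ensemble(x, x, kind=kind, min_samples_leaf=1)
    assert np.max(np.abs(fc.predict(x) - x)) < 0.2
    # predictions stay inside the training response range
    assert fc.predict([20.0, 50.0]).min() >= 30.0
    assert fc.predict([20.0, 50.0]).max() <= 38.0


def test_tree_ensemble_seeded_reproducibility(linear_xy):
    x, y = linear_xy
    a = fit_tree_ensemble(x, y, kind="random_forest", n_estimators=50, seed=3)
    b = fit_tree_ensemble(x, y, kind="random_forest", n_estimators=50, seed=3)
    np.testing.assert_array_equal(a.predict(x), b.predict(x))


# --- spec dispatch and defaults ----------------------------------------------


def test_default_hyperparameters_resolution():
    spec = CalibratorSpec("quantile_gbrt")
    assert spec.resolved() == {"n_estimators": 400, "learning_rate": 0.05,
                               "max_depth": 3}
    override = CalibratorSpec("quantile_gbrt", {"max_depth": 2})
    assert override.resolved()["max_depth"] == 2
    with pytest.raises(ValueError):
        CalibratorSpec("neural_net")


def test_spec_json_round_trip():
    spec = CalibratorSpec("spline_huber", {"n_knots": 4}, seed=7)
    assert CalibratorSpec.from_json(spec.to_json()) == spec


@pytest.mark.parametrize("name", [
    "polynomial_huber", "isotonic", "spline_huber", "loess", "weighted_spline",
    "quantile_gbrt", "monotone_boost", "random_forest", "extra_trees",
])
def test_dispatcher_fits_every_model(name, linear_xy):
    x, y = linear_xy
    hp = {"n_estimators": 50} if "boost" in name or "forest" in name or "trees" in name or name == "quantile_gbrt" else {}
    fc = fit_calibrator(CalibratorSpec(name, hp, seed=0), x, y)
    pred = fc.predict(np.linspace(31, 37, 20))
    assert np.isfinite(pred).all()
    assert np.max(np.abs(pred - np.linspace(31, 37, 20))) < 1.0


def test_dispatcher_deming_needs_table_or_delta(linear_xy, study_table, paired):
    x, y = linear_xy
    with pytest.raises(FitError, match="delta"):
        fit_calibrator(CalibratorSpec("deming"), x, y)
    fc = fit_calibrator(
        CalibratorSpec("deming"),
        paired["t_test"].to_numpy(), paired["t_ref"].to_numpy(),
        measurements=study_table,
    )
    assert np.isfinite(fc.slope)


def test_offset_bias_removed_by_every_calibrator():
    """Pure offset bias: each model's mean prediction error goes to ~0."""
    rng = np.random.default_rng(11)
    x_true = rng.uniform(33, 37, 800)
    t_test = x_true - 1.42 + rng.normal(0, 0.3, 800)
    t_ref = x_true + rng.normal(0, 0.05, 800)
    for name in ["polynomial_huber", "isotonic", "spline_huber", "loess",
                 "weighted_spline", "random_forest", "extra_trees"]:
        fc = fit_calibrator(CalibratorSpec(name, seed=0), t_test, t_ref)
        bias = float(np.mean(fc.predict(t_test) - t_ref))
        assert abs(bias) < 0.1, name
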