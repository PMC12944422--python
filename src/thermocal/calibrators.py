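"""Ten univariate calibration mappings from test-instrument to reference °C.

Each calibrator learns a function ``f`` with ``t_ref ≈ f(t_test)`` under a
uniform contract: :func:`fit_calibrator` takes a :class:`CalibratorSpec`
and training arrays and returns a :class:`FittedCalibrator` whose
``predict`` is defined for all finite inputs.  Quantile models additionally
expose a (2.5%, 50%, 97.5%) triplet; point estimators get their 95%
intervals downstream via split-conformal residual quantiles.

Model families
--------------
* Robust statistical baselines: polynomial ridge under Huber loss;
  Deming errors-in-variables regression (both instruments are noisy, so
  ordinary least squares would attenuate the slope).
* Non-parametric smoothers: isotonic regression (monotone,
  pool-adjacent-violators), natural cubic splines with quantile-spaced
  knots fit by Huber IRLS, LOESS (local linear, tricube weights, bisquare
  robustness passes), and an inverse-variance weighted spline whose
  weights come from binned residual variances of an isotonic pilot fit.
* Tree ensembles: quantile gradient-boosted trees (pinball loss),
  monotone-constrained LightGBM (median under a non-decreasing
  constraint), random forest and extra trees.

Hyperparameter defaults are the selected configurations of the calibration
study this package reproduces; search ranges live in
:mod:`thermocal.evaluation`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import HuberRegressor, LinearRegression
from sklearn.preprocessing import PolynomialFeatures
import lightgbm as lgb

from .io import DEVICE_REFERENCE, DEVICE_TEST

MODEL_NAMES = (
    "polynomial_huber",
    "deming",
    "isotonic",
    "spline_huber",
    "loess",
    "weighted_spline",
    "quantile_gbrt",
    "monotone_boost",
    "random_forest",
    "extra_trees",
)

QUANTILE_TRIPLET = (0.025, 0.5, 0.975)

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "polynomial_huber": {"degree": 2, "epsilon": 1.35, "alpha": 0.0},
    "deming": {"delta": None},  # None: estimate from replicate variances
    "isotonic": {},
    "spline_huber": {"n_knots": 6, "epsilon": 1.35},
    "loess": {"frac": 0.25, "robust_iters": 1},
    "weighted_spline": {"n_knots": 6, "n_bins": 10},
    "quantile_gbrt": {"n_estimators": 400, "learning_rate": 0.05, "max_depth": 3},
    "monotone_boost": {"n_estimators": 600, "learning_rate": 0.03, "num_leaves": 31},
    "random_forest": {"n_estimators": 400, "min_samples_leaf": 5, "bootstrap": True},
    "extra_trees": {"n_estimators": 400, "min_samples_leaf": 5, "bootstrap": False},
}


class FitError(RuntimeError):
    """A calibrator failed to fit (non-convergence, degenerate input)."""


@dataclass(frozen=True)
class CalibratorSpec:
    """Identity + hyperparameters of one calibration model.

    ``hyperparameters`` overrides the model's defaults; ``seed`` drives all
    stochastic fits (tree ensembles) so refits are reproducible.
    """

    model_name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.model_name!r}; choose from {MODEL_NAMES}"
            )

    def resolved(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.model_name], **self.hyperparameters}

    def to_json(self) -> str:
        return json.dumps(
            {"model_name": self.model_name, "hyperparameters": self.hyperparameters,
             "seed": self.seed}
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibratorSpec":
        return cls(**json.loads(text))


def default_specs(seed: int = 0) -> list[CalibratorSpec]:
    """One spec per model, at default hyperparameters."""
    return [CalibratorSpec(name, seed=seed) for name in MODEL_NAMES]


class FittedCalibrator:
    """Fitted mapping with point predictions and optional native intervals.

    ``interval_source`` is ``"quantile_model"`` when the model fits its own
    (2.5%, 50%, 97.5%) triplet, else ``"conformal"`` (intervals supplied by
    the evaluation layer).  ``x_min``/``x_max`` record the training domain;
    :meth:`extrapolation_mask` flags queries outside it.
    """

    def __init__(self, spec, point_model, x, quantile_models=None):
        self.spec = spec
        self._point = point_model
        self._quantiles = quantile_models
        self.x_min = float(np.min(x))
        self.x_max = float(np.max(x))

    @property
    def interval_source(self) -> str:
        return "quantile_model" if self._quantiles is not None else "conformal"

    def predict(self, x_new) -> np.ndarray:
        x = _as_1d(x_new, "x_new")
        return np.asarray(self._point.predict(x.reshape(-1, 1))
                          if _wants_2d(self._point) else self._point.predict(x),
                          dtype=float)

    def predict_quantiles(self, x_new) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lower, median, upper) with quantile crossing repaired by sorting."""
        if self._quantiles is None:
            raise FitError(
                f"{self.spec.model_name} has no native quantile models; "
                "use conformal intervals"
            )
        x = _as_1d(x_new, "x_new")
        preds = []
        for m in self._quantiles:
            p = m.predict(x.reshape(-1, 1)) if _wants_2d(m) else m.predict(x)
            preds.append(np.asarray(p, dtype=float))
        stacked = np.sort(np.vstack(preds), axis=0)
        return stacked[0], stacked[1], stacked[2]

    def extrapolation_mask(self, x_new) -> np.ndarray:
        x = _as_1d(x_new, "x_new")
        return (x < self.x_min) | (x > self.x_max)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} must be finite")
    return arr


def _wants_2d(model) -> bool:
    # sklearn/lightgbm estimators take (n, 1); our own models take (n,)
    return hasattr(model, "get_params")


# ---------------------------------------------------------------------------
# robust statistical baselines


def fit_polynomial_huber(x, y, degree=2, epsilon=1.35, alpha=0.0,
                         spec=None) -> FittedCalibrator:
    """Polynomial basis of ``degree`` under Huber loss with ridge ``alpha``."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) <= degree + 1:
        raise FitError("need n > degree + 1")
    model = _PolyHuber(degree=degree, epsilon=epsilon, alpha=alpha)
    model.fit(x, y)
    spec = spec or CalibratorSpec(
        "polynomial_huber",
        {"degree": degree, "epsilon": epsilon, "alpha": alpha},
    )
    return FittedCalibrator(spec, model, x)


class _PolyHuber:
    def __init__(self, degree, epsilon, alpha):
        self.degree, self.epsilon, self.alpha = degree, epsilon, alpha

    def fit(self, x, y):
        self._poly = PolynomialFeatures(degree=self.degree, include_bias=False)
        X = self._poly.fit_transform(x.reshape(-1, 1))
        # centre/scale columns so the ridge penalty and Huber scale behave
        self._mu, self._sd = X.mean(axis=0), X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        self._huber = HuberRegressor(
            epsilon=self.epsilon, alpha=self.alpha, max_iter=1000
        )
        self._huber.fit((X - self._mu) / self._sd, y)
        return self

    def predict(self, x):
        X = self._poly.transform(np.asarray(x, dtype=float).reshape(-1, 1))
        return self._huber.predict((X - self._mu) / self._sd)

    @property
    def coefficients(self):
        """Polynomial coefficients on the raw scale, constant term first."""
        beta = self._huber.coef_ / self._sd
        intercept = self._huber.intercept_ - float(beta @ self._mu)
        return np.concatenate([[intercept], beta])


def deming_slope_intercept(x, y, delta: float) -> tuple[float, float]:
    """Closed-form Deming line through noisy (x, y).

    ``delta`` is the error-variance ratio Var(y-error)/Var(x-error).  With
    sample (co)variances ``s_xx, s_yy, s_xy``::

        slope = (s_yy - delta*s_xx + sqrt((s_yy - delta*s_xx)^2
                 + 4*delta*s_xy^2)) / (2*s_xy)
        intercept = mean(y) - slope * mean(x)

    As ``delta → ∞`` (all error in y) the slope tends to the ordinary
    regression of y on x; as ``delta → 0`` it tends to the inverse of the
    regression of x on y.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 3:
        raise FitError("Deming needs n >= 3")
    s_xx = np.var(x, ddof=1)
    s_yy = np.var(y, ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    if s_xy == 0:
        raise FitError("zero covariance: Deming slope undefined")
    disc = (s_yy - delta * s_xx) ** 2 + 4 * delta * s_xy**2
    slope = (s_yy - delta * s_xx + np.sqrt(disc)) / (2 * s_xy)
    return float(slope), float(np.mean(y) - slope * np.mean(x))


class _Line:
    def __init__(self, slope, intercept):
        self.slope, self.intercept = slope, intercept

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_deming(x, y, delta: float, spec=None) -> FittedCalibrator:
    """Errors-in-variables straight-line calibration."""
    slope, intercept = deming_slope_intercept(x, y, delta)
    spec = spec or CalibratorSpec("deming", {"delta": delta})
    fc = FittedCalibrator(spec, _Line(slope, intercept), _as_1d(x, "x"))
    fc.slope, fc.intercept = slope, intercept
    return fc


def estimate_error_variance_ratio(table: pd.DataFrame) -> float:
    """Replicate-based error-variance ratio for Deming regression.

    Pools per-(participant, round) replicate variances by averaging across
    cells, separately per device, and returns
    ``reference variance / test variance`` — the ``delta`` orientation the
    Deming slope formula expects when the reference is the response.
    """
    grouped = table.groupby(["participant_id", "round", "device"], sort=False)[
        "temperature_c"
    ]
    if (grouped.size() < 2).any():
        raise FitError("every (participant, round, device) cell needs >= 2 replicates")
    per_cell = grouped.var(ddof=1)
    pooled = per_cell.groupby(level="device").mean()
    if pooled[DEVICE_TEST] == 0:
        raise FitError("zero test-device replicate variance: ratio undefined")
    return float(pooled[DEVICE_REFERENCE] / pooled[DEVICE_TEST])


# ---------------------------------------------------------------------------
# non-parametric smoothers


def fit_isotonic(x, y, weights=None, spec=None) -> FittedCalibrator:
    """Monotone non-decreasing least-squares fit (pool-adjacent-violators).

    Predictions interpolate linearly between fitted knots and extend the
    boundary values outside the training range — a physical-monotonicity
    constraint: a higher raw reading can never map to a lower calibrated
    temperature.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 2:
        raise FitError("isotonic needs n >= 2")
    model = IsotonicRegression(increasing=True, out_of_bounds="clip")
    model.fit(x, y, sample_weight=weights)
    return FittedCalibrator(spec or CalibratorSpec("isotonic"), _Isotonic(model), x)


class _Isotonic:
    def __init__(self, model):
        self._m = model

    def predict(self, x):
        return self._m.predict(np.asarray(x, dtype=float))


class _LgbQuantile:
    """LightGBM pinball-loss booster behind a named single-feature frame.

    The DataFrame round-trip keeps fit/predict feature names consistent so
    scikit-learn's validation stays quiet.
    """

    def __init__(self, alpha, params):
        self.alpha, self.params = alpha, dict(params)

    def fit(self, x, y):
        self._m = lgb.LGBMRegressor(objective="quantile", alpha=self.alpha,
                                    **self.params)
        self._m.fit(pd.DataFrame({"t_test": x}), y)
        return self

    def predict(self, x):
        return self._m.predict(pd.DataFrame({"t_test": np.asarray(x, dtype=float).ravel()}))


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Truncated-power construction with the natural constraints absorbed:
    columns are ``1, x, N_1(x) … N_{K-2}(x)`` where
    ``N_k = d_k - d_{K-1}`` and
    ``d_k(x) = ((x - ξ_k)_+^3 - (x - ξ_K)_+^3) / (ξ_K - ξ_k)``.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    cols = [np.ones_like(x), x]
    if K >= 3:
        def d(k):
            return (
                np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[-1], 0, None) ** 3
            ) / (knots[-1] - knots[k])

        d_last = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - d_last)
    return np.column_stack(cols)


def _quantile_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    knots = np.quantile(x, np.linspace(0, 1, n_knots))
    knots = np.unique(knots)  # collapse ties from discretised data
    if len(knots) < 2:
        raise FitError("degenerate x: cannot place spline knots")
    return knots


class _SplineModel:
    def __init__(self, knots, coefs):
        self.knots, self.coefs = knots, coefs

    def predict(self, x):
        return natural_cubic_basis(np.asarray(x, dtype=float), self.knots) @ self.coefs


def _huber_irls(X, y, epsilon, tol=1e-8, max_iter=200, base_weights=None):
    """Iteratively reweighted least squares under Huber loss.

    Scale is re-estimated each pass as 1.4826 × median absolute residual;
    converges when the max coefficient change drops below ``tol``.
    """
    w0 = np.ones(len(y)) if base_weights is None else np.asarray(base_weights, float)
    coefs = np.linalg.lstsq(X * np.sqrt(w0)[:, None], y * np.sqrt(w0), rcond=None)[0]
    for _ in range(max_iter):
        resid = y - X @ coefs
        scale = 1.4826 * np.median(np.abs(resid))
        if scale == 0:
            return coefs  # exact fit
        z = np.abs(resid) / (epsilon * scale)
        w = w0 * np.where(z <= 1.0, 1.0, 1.0 / z)
        sw = np.sqrt(w)
        new = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
        if np.max(np.abs(new - coefs)) < tol:
            return new
        coefs = new
    raise FitError(f"Huber IRLS did not converge in {max_iter} iterations")


def fit_spline_huber(x, y, n_knots=6, epsilon=1.35, spec=None) -> FittedCalibrator:
    """Natural cubic spline (quantile-spaced knots) under robust Huber loss."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) <= n_knots + 2:
        raise FitError("need n > n_knots + 2")
    knots = _quantile_knots(x, n_knots)
    X = natural_cubic_basis(x, knots)
    coefs = _huber_irls(X, y, epsilon)
    spec = spec or CalibratorSpec("spline_huber", {"n_knots": n_knots, "epsilon": epsilon})
    return FittedCalibrator(spec, _SplineModel(knots, coefs), x)


class _Loess:
    """Local linear regression with tricube weights and bisquare robustness."""

    def __init__(self, frac, robust_iters):
        self.frac, self.robust_iters = frac, robust_iters

    def fit(self, x, y):
        self.x_, self.y_ = x, y
        n = len(x)
        self.q_ = max(int(np.ceil(self.frac * n)), 3)
        if self.q_ > n:
            raise FitError("frac * n must be >= 3 and <= n")
        self.robust_w_ = np.ones(n)
        for _ in range(self.robust_iters):
            resid = y - self._smooth(x)
            m = np.median(np.abs(resid))
            if m == 0:
                break
            u = resid / (6.0 * m)
            self.robust_w_ = np.clip(1 - u**2, 0, None) ** 2
        return self

    def _fit_at(self, x0: float) -> float:
        dist = np.abs(self.x_ - x0)
        idx = np.argsort(dist, kind="stable")[: self.q_]
        h = dist[idx].max()
        if h == 0:
            if np.ptp(self.x_[idx]) == 0 and len(np.unique(self.x_)) > 1:
                raise FitError(f"degenerate neighborhood at x={x0}: all same x")
            return float(np.average(self.y_[idx], weights=self.robust_w_[idx] + 1e-12))
        w = np.clip(1 - (dist[idx] / h) ** 3, 0, None) ** 3 * self.robust_w_[idx]
        if w.sum() == 0:
            w = np.ones_like(w)
        xi, yi = self.x_[idx], self.y_[idx]
        xbar = np.average(xi, weights=w)
        sxx = np.sum(w * (xi - xbar) ** 2)
        if sxx == 0:
            raise FitError(f"degenerate neighborhood at x={x0}: all same x")
        slope = np.sum(w * (xi - xbar) * yi) / sxx
        return float(np.average(yi, weights=w) + slope * (x0 - xbar))

    def _smooth(self, xs):
        return np.array([self._fit_at(v) for v in np.asarray(xs, dtype=float)])

    def predict(self, x):
        return self._smooth(x)


def fit_loess(x, y, frac=0.25, robust_iters=1, spec=None) -> FittedCalibrator:
    """LOESS: local degree-1 fits over the nearest ``frac·n`` neighbours."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    model = _Loess(frac, robust_iters).fit(x, y)
    spec = spec or CalibratorSpec("loess", {"frac": frac, "robust_iters": robust_iters})
    return FittedCalibrator(spec, model, x)


def fit_weighted_spline(x, y, n_knots=6, n_bins=10, var_floor=1e-6,
                        spec=None) -> FittedCalibrator:
    """Heteroscedasticity-aware spline: inverse-variance weights from a pilot.

    Stage 1 fits an isotonic pilot; stage 2 bins x into ``n_bins``
    equal-count bins and estimates the pilot-residual variance per bin
    (floored at ``var_floor`` °C²); stage 3 fits a weighted least-squares
    natural cubic spline with weights 1/variance.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 2 * n_bins:
        n_bins = max(len(x) // 2, 1)
    pilot = fit_isotonic(x, y)
    resid = y - pilot.predict(x)
    order = np.argsort(x, kind="stable")
    bins = np.array_split(order, n_bins)
    weights = np.empty_like(x)
    for b in bins:
        v = max(float(np.var(resid[b])), var_floor)
        weights[b] = 1.0 / v
    knots = _quantile_knots(x, n_knots)
    X = natural_cubic_basis(x, knots)
    sw = np.sqrt(weights)
    coefs = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
    spec = spec or CalibratorSpec("weighted_spline", {"n_knots": n_knots, "n_bins": n_bins})
    fc = FittedCalibrator(spec, _SplineModel(knots, coefs), x)
    fc.bin_weights = weights
    return fc


# ---------------------------------------------------------------------------
# tree ensembles


def fit_quantile_boost(
    x, y, quantiles=QUANTILE_TRIPLET, n_estimators=400, learning_rate=0.05,
    max_depth=3, seed=0, spec=None,
) -> FittedCalibrator:
    """Gradient-boosted trees per quantile, minimising pinball loss.

    Point prediction is the 0.5-quantile model; the (0.025, 0.975) models
    supply native 95% intervals, with crossings repaired by per-point
    sorting.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 20:
        raise FitError("quantile boosting needs n >= 20")
    if any(not 0 < q < 1 for q in quantiles):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    X = x.reshape(-1, 1)
    models = []
    for q in sorted(quantiles):
        m = GradientBoostingRegressor(
            loss="quantile", alpha=q, n_estimators=n_estimators,
            learning_rate=learning_rate, max_depth=max_depth, random_state=seed,
        )
        m.fit(X, y)
        models.append(m)
    spec = spec or CalibratorSpec(
        "quantile_gbrt",
        {"n_estimators": n_estimators, "learning_rate": learning_rate,
         "max_depth": max_depth},
        seed=seed,
    )
    return FittedCalibrator(spec, models[1], x, quantile_models=models)


def fit_monotone_boost(
    x, y, n_estimators=600, learning_rate=0.03, num_leaves=31, seed=0, spec=None,
) -> FittedCalibrator:
    """LightGBM median booster with an exact non-decreasing guarantee.

    A 0.5-pinball (conditional-median) LightGBM model is fit first; its
    fitted curve is then projected onto the cone of non-decreasing
    functions by isotonic regression on the training grid (monotone
    rearrangement).  Gradient-boosting libraries cannot enforce hard
    monotone constraints under non-smooth pinball objectives, and the
    projection is the exact least-squares monotonisation of the boosted
    curve, so predictions on any sorted grid are non-decreasing by
    construction.  Unconstrained 0.025/0.975 quantile models provide the
    uncertainty interval.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 20:
        raise FitError("monotone boosting needs n >= 20")
    common = dict(
        n_estimators=n_estimators, learning_rate=learning_rate,
        num_leaves=num_leaves, random_state=seed, verbose=-1,
        min_child_samples=5,
    )
    booster = _LgbQuantile(0.5, common).fit(x, y)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(x, booster.predict(x))
    median = _Isotonic(iso)
    lower = _LgbQuantile(0.025, common).fit(x, y)
    upper = _LgbQuantile(0.975, common).fit(x, y)
    spec = spec or CalibratorSpec(
        "monotone_boost",
        {"n_estimators": n_estimators, "learning_rate": learning_rate,
         "num_leaves": num_leaves},
        seed=seed,
    )
    return FittedCalibrator(spec, median, x, quantile_models=[lower, median, upper])


def fit_tree_ensemble(
    x, y, kind="random_forest", n_estimators=400, min_samples_leaf=5,
    bootstrap=True, seed=0, spec=None,
) -> FittedCalibrator:
    """Bagged (random forest) or fully randomised (extra trees) ensemble."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 10:
        raise FitError("tree ensembles need n >= 10")
    cls = {"random_forest": RandomForestRegressor, "extra_trees": ExtraTreesRegressor}
    if kind not in cls:
        raise ValueError(f"kind must be one of {sorted(cls)}")
    model = cls[kind](
        n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
        bootstrap=bootstrap, random_state=seed,
    )
    model.fit(x.reshape(-1, 1), y)
    spec = spec or CalibratorSpec(
        kind,
        {"n_estimators": n_estimators, "min_samples_leaf": min_samples_leaf,
         "bootstrap": bootstrap},
        seed=seed,
    )
    return FittedCalibrator(spec, model, x)


# ---------------------------------------------------------------------------
# dispatcher


def fit_calibrator(spec: CalibratorSpec, x, y,
                   measurements: pd.DataFrame | None = None) -> FittedCalibrator:
    """Fit any of the ten models from its spec.

    ``measurements`` (the raw long-format table) is only needed for Deming
    when ``delta`` is unset, to estimate the error-variance ratio from
    within-participant replicate variances.
    """
    hp = spec.resolved()
    name = spec.model_name
    if name == "polynomial_huber":
        return fit_polynomial_huber(x, y, spec=spec, **hp)
    if name == "deming":
        delta = hp["delta"]
        if delta is None:
            if measurements is None:
                raise FitError(
                    "Deming needs either an explicit delta or the raw "
                    "measurement table to estimate it from replicates"
                )
            delta = estimate_error_variance_ratio(measurements)
        return fit_deming(x, y, delta, spec=spec)
    if name == "isotonic":
        return fit_isotonic(x, y, spec=spec)
    if name == "spline_huber":
        return fit_spline_huber(x, y, spec=spec, **hp)
    if name == "loess":
        return fit_loess(x, y, spec=spec, **hp)
    if name == "weighted_spline":
        return fit_weighted_spline(x, y, spec=spec, **hp)
    if name == "quantile_gbrt":
        return fit_quantile_boost(x, y, seed=spec.seed, spec=spec, **hp)
    if name == "monotone_boost":
        return fit_monotone_boost(x, y, seed=spec.seed, spec=spec, **hp)
    return fit_tree_ensemble(x, y, kind=name, seed=spec.seed, spec=spec, **hp)
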