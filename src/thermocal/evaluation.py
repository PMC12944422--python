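"""Leakage-free evaluation of the calibration suite.

All model assessment uses grouped k-fold cross-validation keyed on the
participant: every replicate of a participant stays on one side of each
split, because replicates of the same subject are strongly dependent and
row-wise CV would leak that dependence into the test folds, flattering
every model.  Metrics (MAE, RMSE, R², bias, Bland–Altman LoA of
prediction errors) are computed on the pooled out-of-fold predictions.

95% prediction intervals come from (a) the quantile models directly, or
(b) split-conformal absolute-residual quantiles for point estimators:
``point ± q`` with ``q`` the ⌈(m+1)(1−α)⌉-th smallest calibration
residual, which guarantees ≥ 1−α marginal coverage for exchangeable data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import LOA_MULTIPLIER
from .calibrators import CalibratorSpec, FittedCalibrator, fit_calibrator

MIN_TRAIN_SIZE = 10

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "polynomial_huber": {
        "degree": [1, 2, 3],
        "alpha": [0.0001, 0.001, 0.01],
        "epsilon": [1.1, 1.35, 1.5, 1.7],
    },
    "spline_huber": {"n_knots": [3, 4, 5, 6, 8], "epsilon": [1.2, 1.35, 1.5]},
    "loess": {"frac": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], "robust_iters": [0, 1, 3]},
    "quantile_gbrt": {
        "n_estimators": [100, 300, 500],
        "learning_rate": [0.01, 0.05, 0.1],
        "max_depth": [2, 3],
    },
    "monotone_boost": {
        "n_estimators": [100, 300, 500],
        "learning_rate": [0.01, 0.05, 0.1],
        "num_leaves": [7, 15, 31],
    },
    "random_forest": {
        "n_estimators": [100, 300, 500],
        "min_samples_leaf": [1, 3, 5],
        "bootstrap": [True, False],
    },
    "extra_trees": {
        "n_estimators": [100, 300, 500],
        "min_samples_leaf": [1, 3, 5],
        "bootstrap": [True, False],
    },
}


@dataclass(frozen=True)
class FoldAssignment:
    """Participant → fold map for grouped cross-validation."""

    fold_of: dict[str, int]
    k: int

    def participants(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of.items() if f == fold]


@dataclass(frozen=True)
class CalibrationMetrics:
    model_name: str
    mae_c: float
    rmse_c: float
    r2: float
    bias_c: float
    loa_lower_c: float
    loa_upper_c: float
    n: int


@dataclass(frozen=True)
class PredictionWithInterval:
    point: float
    lower: float
    upper: float
    interval_source: str  # "quantile_model" | "conformal"


def group_kfold(participants, k: int, seed: int = 0) -> FoldAssignment:
    """Deterministically shuffle participants into k near-equal folds.

    Fold sizes differ by at most one; every participant lands in exactly
    one fold.
    """
    parts = list(dict.fromkeys(participants))  # unique, order-preserving
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(parts):
        raise ValueError(f"k={k} exceeds number of participants ({len(parts)})")
    order = np.random.default_rng(seed).permutation(len(parts))
    fold_of = {parts[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(fold_of=fold_of, k=k)


def cross_validated_predictions(
    paired: pd.DataFrame,
    spec: CalibratorSpec,
    folds: FoldAssignment,
    measurements: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Out-of-fold predictions: each row predicted by a model that never saw
    any row of that participant.

    Returns ``paired`` plus a ``y_pred`` column.  When a raw measurement
    table is supplied (needed by Deming's variance-ratio estimate), it too
    is restricted to the training participants of each fold.
    """
    fold_ids = paired["participant_id"].map(folds.fold_of)
    if fold_ids.isna().any():
        missing = paired.loc[fold_ids.isna(), "participant_id"].unique().tolist()
        raise ValueError(f"participants without a fold: {missing[:5]}")
    y_pred = np.full(len(paired), np.nan)
    for fold in range(folds.k):
        test_mask = (fold_ids == fold).to_numpy()
        train = paired[~test_mask]
        test = paired[test_mask]
        if len(test) == 0:
            continue
        assert not set(train["participant_id"]) & set(test["participant_id"])
        if len(train) < MIN_TRAIN_SIZE:
            raise ValueError(f"fold {fold}: only {len(train)} training rows")
        meas = None
        if measurements is not None:
            meas = measurements[
                measurements["participant_id"].isin(set(train["participant_id"]))
            ]
        fitted = fit_calibrator(
            spec, train["t_test"].to_numpy(), train["t_ref"].to_numpy(),
            measurements=meas,
        )
        y_pred[test_mask] = fitted.predict(test["t_test"].to_numpy())
    out = paired.copy()
    out["y_pred"] = y_pred
    return out


def compute_metrics(y_true, y_pred, model_name: str = "") -> CalibrationMetrics:
    """Error metrics with the error defined as ``e = y_pred - y_true``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need equal-length arrays with n >= 2")
    e = y_pred - y_true
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    bias = float(np.mean(e))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_true: R^2 undefined")
    r2 = 1.0 - float(np.sum(e**2)) / ss_tot
    sd = float(np.std(e, ddof=1))
    return CalibrationMetrics(
        model_name=model_name,
        mae_c=mae,
        rmse_c=rmse,
        r2=r2,
        bias_c=bias,
        loa_lower_c=bias - LOA_MULTIPLIER * sd,
        loa_upper_c=bias + LOA_MULTIPLIER * sd,
        n=len(e),
    )


def conformal_quantile(calibration_abs_residuals, alpha: float = 0.05) -> float:
    """Finite-sample conformal radius.

    The ⌈(m+1)(1−α)⌉-th smallest of ``m`` absolute calibration residuals;
    ``inf`` when that index exceeds ``m`` (the calibration set is too small
    to certify the requested level).
    """
    r = np.sort(np.asarray(calibration_abs_residuals, dtype=float))
    m = len(r)
    if m == 0:
        raise ValueError("empty calibration residuals")
    rank = int(np.ceil((m + 1) * (1 - alpha)))
    if rank > m:
        return float("inf")
    return float(r[rank - 1])


def conformal_interval(
    point_preds, calibration_abs_residuals, alpha: float = 0.05
) -> list[PredictionWithInterval]:
    """Symmetric split-conformal intervals ``point ± q`` at level 1−α."""
    q = conformal_quantile(calibration_abs_residuals, alpha)
    return [
        PredictionWithInterval(float(p), float(p - q), float(p + q), "conformal")
        for p in np.asarray(point_preds, dtype=float)
    ]


def _metrics_from_oof(oof: pd.DataFrame, name: str) -> CalibrationMetrics:
    return compute_metrics(oof["t_ref"].to_numpy(), oof["y_pred"].to_numpy(), name)


def grid_search(
    paired: pd.DataFrame,
    model_name: str,
    folds: FoldAssignment,
    grid: dict[str, list] | None = None,
    measurements: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[CalibratorSpec, pd.DataFrame]:
    """Exhaustive hyperparameter search on out-of-fold MAE.

    Ties break on lower RMSE, then first-in-grid order.  Returns the
    winning spec and the full per-configuration results table.
    """
    grid = DEFAULT_GRIDS.get(model_name, {}) if grid is None else grid
    names = list(grid)
    combos = list(itertools.product(*(grid[n] for n in names))) if names else [()]
    if not combos:
        raise ValueError("empty grid")
    rows = []
    best = None
    for i, combo in enumerate(combos):
        hp = dict(zip(names, combo))
        spec = CalibratorSpec(model_name, hp, seed=seed)
        oof = cross_validated_predictions(paired, spec, folds, measurements)
        m = _metrics_from_oof(oof, model_name)
        rows.append({**hp, "mae_c": m.mae_c, "rmse_c": m.rmse_c, "r2": m.r2,
                     "bias_c": m.bias_c})
        key = (m.mae_c, m.rmse_c, i)
        if best is None or key < best[0]:
            best = (key, spec)
    return best[1], pd.DataFrame(rows)


class DeployedCalibrator:
    """Full-data refit plus its 95% prediction-interval machinery."""

    def __init__(self, fitted: FittedCalibrator, conformal_q: float | None,
                 alpha: float):
        self.fitted = fitted
        self.conformal_q = conformal_q
        self.alpha = alpha

    @property
    def interval_source(self) -> str:
        return self.fitted.interval_source

    def predict(self, x_new) -> np.ndarray:
        return self.fitted.predict(x_new)

    def predict_with_interval(self, x_new) -> list[PredictionWithInterval]:
        if self.fitted.interval_source == "quantile_model":
            lo, mid, hi = self.fitted.predict_quantiles(x_new)
            return [
                PredictionWithInterval(float(m), float(l), float(h), "quantile_model")
                for l, m, h in zip(lo, mid, hi)
            ]
        point = self.fitted.predict(x_new)
        return [
            PredictionWithInterval(float(p), float(p - self.conformal_q),
                                   float(p + self.conformal_q), "conformal")
            for p in point
        ]


def fit_deployment(
    paired: pd.DataFrame,
    spec: CalibratorSpec,
    folds: FoldAssignment | None = None,
    measurements: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DeployedCalibrator:
    """Refit on all rows; wire up intervals.

    Quantile models carry their own interval; point estimators get a
    conformal radius calibrated on out-of-fold absolute residuals (so the
    calibration residuals are exchangeable with deployment errors, not
    optimistically in-sample).
    """
    x = paired["t_test"].to_numpy()
    y = paired["t_ref"].to_numpy()
    fitted = fit_calibrator(spec, x, y, measurements=measurements)
    q = None
    if fitted.interval_source == "conformal":
        if folds is None:
            folds = group_kfold(paired["participant_id"], k=min(5, paired["participant_id"].nunique()))
        oof = cross_validated_predictions(paired, spec, folds, measurements)
        q = conformal_quantile(np.abs(oof["y_pred"] - oof["t_ref"]), alpha)
    return DeployedCalibrator(fitted, q, alpha)


def run_calibration_suite(
    paired: pd.DataFrame,
    specs: list[CalibratorSpec],
    folds: FoldAssignment,
    measurements: pd.DataFrame | None = None,
    include_raw: bool = True,
) -> pd.DataFrame:
    """Out-of-fold metrics for every spec, plus an uncalibrated baseline row.

    All models share the same fold assignment, so rows are directly
    comparable.  The ``raw`` row scores the uncorrected test-instrument
    reading against the reference.
    """
    rows = []
    if include_raw:
        m = compute_metrics(paired["t_ref"].to_numpy(), paired["t_test"].to_numpy(),
                            "raw")
        rows.append(m)
    for spec in specs:
        oof = cross_validated_predictions(paired, spec, folds, measurements)
        rows.append(_metrics_from_oof(oof, spec.model_name))
    return pd.DataFrame(
        [
            {
                "model": m.model_name, "mae_c": m.mae_c, "rmse_c": m.rmse_c,
                "r2": m.r2, "bias_c": m.bias_c, "loa_lower_c": m.loa_lower_c,
                "loa_upper_c": m.loa_upper_c, "n": m.n,
            }
            for m in rows
        ]
    )
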