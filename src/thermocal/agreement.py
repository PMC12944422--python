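"""Precision, bias, agreement and reliability statistics for paired devices.

The central quantity is the paired difference ``d = t_test - t_ref``.
Bias is its mean, the 95% limits of agreement (LoA) are
``bias ± 1.96 · SD(d)``, and reliability is summarised by ICC(2,1) — the
two-way random-effects, absolute-agreement, single-measurement intraclass
correlation, which (unlike consistency forms) penalises a systematic
offset between instruments.

Two analysis levels are supported everywhere a choice exists:

* ``participant_means`` (default) — one unit per participant, using the
  per-participant mean reading of each device within a round.  This is the
  level at which a single bias/LoA per round is conventionally reported in
  method-comparison studies with replicated measurements.
* ``replicates`` — every replicate pair is a unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEVICE_REFERENCE, DEVICE_TEST

LOA_MULTIPLIER = 1.96
LEVELS = ("participant_means", "replicates")


class DegenerateDataError(ValueError):
    """Statistic undefined for this input (zero variance, too few units)."""


@dataclass(frozen=True)
class PrecisionSummary:
    """Intra-participant SDs: the study's precision/repeatability metric."""

    per_cell: pd.DataFrame  # columns: participant_id, round, device, sd_c
    mean_sd: pd.DataFrame  # columns: round, device, mean_sd_c


@dataclass(frozen=True)
class AgreementSummary:
    round: str
    level: str
    bias_c: float
    sd_diff_c: float
    loa_lower_c: float
    loa_upper_c: float
    loa_range_c: float
    icc_2_1: float
    pearson_r: float
    t_statistic: float
    p_value: float
    n_units: int
    points: pd.DataFrame  # per-unit (mean, diff) for Bland-Altman plotting


def intra_participant_sd(table: pd.DataFrame) -> PrecisionSummary:
    """Sample SD (n−1) of replicates per (participant, device, round).

    Raises :class:`DegenerateDataError` naming the first cell with fewer
    than two replicates.
    """
    grouped = table.groupby(["participant_id", "round", "device"], sort=False)[
        "temperature_c"
    ]
    counts = grouped.size()
    thin = counts[counts < 2]
    if len(thin):
        raise DegenerateDataError(
            f"cell(s) with < 2 replicates: {thin.index.tolist()[:5]}"
        )
    per_cell = grouped.std(ddof=1).rename("sd_c").reset_index()
    mean_sd = (
        per_cell.groupby(["round", "device"], sort=False)["sd_c"]
        .mean()
        .rename("mean_sd_c")
        .reset_index()
    )
    return PrecisionSummary(per_cell=per_cell, mean_sd=mean_sd)


def _units(paired: pd.DataFrame, round: str | None, level: str) -> pd.DataFrame:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    sub = paired if round is None else paired[paired["round"] == round]
    if level == "participant_means":
        units = (
            sub.groupby("participant_id", sort=False)[["t_test", "t_ref"]]
            .mean()
            .reset_index()
        )
        units["diff"] = units["t_test"] - units["t_ref"]
    else:
        units = sub[["participant_id", "t_test", "t_ref", "diff"]].copy()
    units["mean"] = (units["t_test"] + units["t_ref"]) / 2.0
    return units


def bland_altman(
    paired: pd.DataFrame, round: str | None = None, level: str = "participant_means"
) -> AgreementSummary:
    """Bland–Altman agreement analysis for one round (or pooled rounds).

    Returns bias, SD of differences, 95% LoA (bias ± 1.96·SD and their
    range), ICC(2,1) on the units' (test, reference) matrix, Pearson r,
    and the paired t-test, plus the per-unit (mean, diff) points.
    """
    units = _units(paired, round, level)
    d = units["diff"].to_numpy(dtype=float)
    if len(d) < 2:
        raise DegenerateDataError("need >= 2 analysis units")
    if not np.isfinite(d).all():
        raise DegenerateDataError("non-finite differences")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lower = bias - LOA_MULTIPLIER * sd
    upper = bias + LOA_MULTIPLIER * sd
    matrix = units[["t_test", "t_ref"]].to_numpy(dtype=float)
    try:
        icc = icc_absolute_agreement(matrix)
    except DegenerateDataError:
        icc = float("nan")
    if sd > 0:
        t, p, _ = paired_t(units["t_test"].to_numpy(), units["t_ref"].to_numpy())
    else:
        t, p = float("nan"), float("nan")
    if units["t_test"].std() > 0 and units["t_ref"].std() > 0:
        r = float(stats.pearsonr(units["t_test"], units["t_ref"]).statistic)
    else:
        r = float("nan")
    return AgreementSummary(
        round=round if round is not None else "pooled",
        level=level,
        bias_c=bias,
        sd_diff_c=sd,
        loa_lower_c=lower,
        loa_upper_c=upper,
        loa_range_c=upper - lower,
        icc_2_1=icc,
        pearson_r=r,
        t_statistic=t,
        p_value=p,
        n_units=len(d),
        points=units[["participant_id", "mean", "diff"]].copy(),
    )


def icc_absolute_agreement(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix`` is n_subjects × k_raters.  Computed from the two-way mean
    squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR, MSC, MSE the subject (row), rater (column) and residual mean
    squares of the complete two-way layout.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateDataError("ICC needs >= 2 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise DegenerateDataError("ICC needs a complete matrix")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Paired-samples t-test on ``d = a - b``; returns (t, p, df)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return one_sample_t(d, 0.0)


def one_sample_t(values: np.ndarray, null_mean: float) -> tuple[float, float, int]:
    """One-sample t-test against ``null_mean``; returns (t, p, df)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DegenerateDataError("t-test needs n >= 2")
    if np.std(v, ddof=1) == 0:
        raise DegenerateDataError("zero-variance sample: t-test degenerate")
    res = stats.ttest_1samp(v, null_mean)
    return float(res.statistic), float(res.pvalue), len(v) - 1


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality check; returns (W, p, pass at ``alpha``)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise DegenerateDataError("Shapiro-Wilk needs n >= 3")
    if np.ptp(v) == 0:
        raise DegenerateDataError("constant sample: normality test undefined")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue >= alpha)


def pearson_within_round(
    paired: pd.DataFrame, round: str | None = None, level: str = "participant_means"
) -> float:
    """Pearson correlation of (t_test, t_ref) at the chosen analysis level."""
    units = _units(paired, round, level)
    if len(units) < 3:
        raise DegenerateDataError("Pearson needs >= 3 units")
    if units["t_test"].std() == 0 or units["t_ref"].std() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    return float(stats.pearsonr(units["t_test"], units["t_ref"]).statistic)


def round_change_correlation(
    paired: pd.DataFrame, rounds: tuple[str, str] = ("R1", "R2")
) -> tuple[float, float]:
    """Correlation of the devices' per-participant between-round shifts.

    For each participant, the change in mean reading from the first to the
    second round is computed for each device; returns the Pearson (r, p)
    between the two devices' change vectors.  A near-zero r means the
    instruments respond to the environmental change independently.
    """
    means = paired.groupby(["participant_id", "round"], sort=False)[
        ["t_test", "t_ref"]
    ].mean()
    deltas = []
    for pid in paired["participant_id"].drop_duplicates():
        try:
            first, second = means.loc[(pid, rounds[0])], means.loc[(pid, rounds[1])]
        except KeyError:
            raise DegenerateDataError(f"participant {pid!r} missing a round")
        deltas.append((second["t_test"] - first["t_test"],
                       second["t_ref"] - first["t_ref"]))
    dt, dr = np.array(deltas).T
    res = stats.pearsonr(dt, dr)
    return float(res.statistic), float(res.pvalue)


def anova_bias_by_group(
    per_participant_bias: np.ndarray, group_labels: np.ndarray
) -> tuple[float, float]:
    """One-way ANOVA of per-participant mean bias across a grouping factor."""
    bias = np.asarray(per_participant_bias, dtype=float)
    labels = np.asarray(group_labels)
    groups = [bias[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DegenerateDataError("ANOVA needs >= 2 groups with >= 2 members each")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def agreement_table(
    paired: pd.DataFrame,
    table: pd.DataFrame | None = None,
    rounds: tuple[str, ...] = ("R1", "R2"),
    level: str = "participant_means",
) -> pd.DataFrame:
    """Publication-shaped per-round summary (rows = statistics, cols = rounds).

    Includes mean temperature, mean intra-participant SD per device (when
    the raw table is supplied), bias, LoA bounds and range, ICC(2,1) and
    Pearson r.
    """
    cols = {}
    precision = intra_participant_sd(table) if table is not None else None
    for r in rounds:
        summ = bland_altman(paired, round=r, level=level)
        sub = paired[paired["round"] == r]
        col = {
            "mean_temperature_c": float(
                pd.concat([sub["t_test"], sub["t_ref"]]).mean()
            ),
            "bias_c": summ.bias_c,
            "loa_lower_c": summ.loa_lower_c,
            "loa_upper_c": summ.loa_upper_c,
            "loa_range_c": summ.loa_range_c,
            "icc_2_1": summ.icc_2_1,
            "pearson_r": summ.pearson_r,
        }
        if precision is not None:
            m = precision.mean_sd.set_index(["round", "device"])["mean_sd_c"]
            col["mean_intra_participant_sd_ref_c"] = float(m.loc[(r, DEVICE_REFERENCE)])
            col["mean_intra_participant_sd_test_c"] = float(m.loc[(r, DEVICE_TEST)])
        cols[r] = col
    return pd.DataFrame(cols)
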