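"""Bland–Altman plotting."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def ba_plot(
    points: pd.DataFrame,
    bias: float,
    loa_lower: float,
    loa_upper: float,
    path,
    title: str = "Bland–Altman",
    trend: bool = True,
) -> None:
    """Scatter of difference vs pairwise mean with bias and LoA lines.

    ``points`` needs ``mean`` and ``diff`` columns (°C).  When ``trend`` is
    on and the means vary, the least-squares trend of diff on mean is drawn
    and its slope annotated — a negative slope is the signature of
    temperature-dependent bias (over-reading cool skin, under-reading warm).
    """
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(points["mean"], points["diff"], s=18, alpha=0.7, edgecolor="none")
    ax.axhline(bias, color="tab:blue", lw=1.2, label=f"bias {bias:+.2f} °C")
    for y, lbl in ((loa_lower, f"LoA {loa_lower:+.2f}"), (loa_upper, f"LoA {loa_upper:+.2f}")):
        ax.axhline(y, color="tab:red", lw=1.0, ls="--", label=lbl)
    if trend and points["mean"].nunique() > 1:
        slope, intercept = np.polyfit(points["mean"], points["diff"], 1)
        xs = np.linspace(points["mean"].min(), points["mean"].max(), 50)
        ax.plot(xs, slope * xs + intercept, color="gray", lw=1,
                label=f"trend slope {slope:+.2f}/°C")
    ax.set_xlabel("mean of paired readings (°C)")
    ax.set_ylabel("difference, test − reference (°C)")
    ax.set_title(title)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
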