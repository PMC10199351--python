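"""Figure renderers: calibration plots and risk-magnification plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import CalibrationReport
from .magnification import MagnificationCurve


def calibration_plot(report: CalibrationReport, path, title: str = "") -> None:
    """Observed (KM, with 95% whiskers) vs mean estimated risk across deciles,
    with the identity line."""
    g = report.groups
    se = np.sqrt(g["greenwood_var"])
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(0.05, float((g["observed"] + 1.96 * se).max()), float(g["mean_estimated"].max())) * 1.1
    ax.plot([0, lim], [0, lim], color="tab:blue", lw=1)
    ax.errorbar(g["mean_estimated"], g["observed"], yerr=1.96 * se, fmt="o",
                color="black", ms=4, capsize=2)
    label = f"MAE={report.mae:.3f}"
    if report.gnd_p is not None:
        label += f", GND p={report.gnd_p:.2f}"
    if report.c_statistic is not None:
        label += f", C={report.c_statistic:.2f}"
    ax.set_xlabel("Mean estimated risk")
    ax.set_ylabel("Observed risk (Kaplan-Meier)")
    ax.set_title(f"{title}\n{label}".strip())
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def magnification_plot(curve: MagnificationCurve, path, title: str = "") -> None:
    """Estimated RD vs baseline risk: smoothed curve with bootstrap band,
    constant-HR reference, quartile overlay points and a baseline-risk
    histogram."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.fill_between(curve.grid, curve.band_lower, curve.band_upper,
                    color="0.85", label="95% band")
    ax.plot(curve.grid, curve.rd, color="tab:blue", label="model-estimated RD")
    ax.plot(curve.grid, curve.reference, color="tab:orange",
            label=f"constant HR={curve.overall_hr:.2f}")
    q = curve.quartiles
    ax.errorbar(q["mean_baseline_risk"], q["observed_rd"],
                yerr=[q["observed_rd"] - q["ci_lower"], q["ci_upper"] - q["observed_rd"]],
                fmt="o", color="tab:blue", mfc="white", capsize=2,
                label="observed RD (quartiles)")
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("Estimated baseline (standard-arm) risk")
    ax.set_ylabel("Risk difference, intensive - standard")
    if curve.linearity_p is not None:
        title = f"{title} (P={curve.linearity_p:.2f} for linearity)".strip()
    ax.set_title(title)
    ax.legend(fontsize=8, loc="lower left")
    hist_ax = ax.twinx()
    hist_ax.hist(curve.baseline_risk, bins=40, color="tab:gray", alpha=0.25)
    hist_ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
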