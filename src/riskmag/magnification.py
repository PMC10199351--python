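"""Benefit-heterogeneity surface: tertile validation tables, risk-
magnification curves with a constant-HR reference and bootstrap bands,
the interaction linearity test, and the hybrid risk+effect model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .cohort import INTENSIVE, Cohort
from .coxnet import PenaltySpec
from .evaluation import harrell_c
from .modified import (
    ModifiedCoxFit,
    absolute_risk,
    estimated_risk_difference,
    fit_modified_model,
)
from .survival import km_group_risk_difference


# ---------------------------------------------------------------------------
# tertile benefit table
# ---------------------------------------------------------------------------

@dataclass
class TertileBenefitTable:
    """Per-tertile-of-estimated-benefit validation against observed KM risk
    differences (the Table-2-style check).  ``table`` rows are ordered
    high / medium / low estimated benefit (most-negative RD first)."""

    table: pd.DataFrame
    t_star: float


def tertile_benefit_table(fit: ModifiedCoxFit, cohort: Cohort,
                          t_star: float | None = None) -> TertileBenefitTable:
    """Split the cohort into tertiles of subject-level estimated risk
    difference; per tertile report arm sizes, raw event counts with
    percentages, the median estimated RD, the observed KM RD at t_star with
    its 95% CI, and estimated-minus-observed."""
    t_star = fit.t_star if t_star is None else t_star
    rd = estimated_risk_difference(fit, cohort, t_star)
    times, events = cohort.outcome_arrays(fit.outcome)
    intensive = cohort.intensive_mask

    order = np.argsort(rd, kind="mergesort")  # most negative (high benefit) first
    labels = ("high", "medium", "low")
    rows = []
    for label, chunk in zip(labels, np.array_split(order, 3)):
        in_t = intensive[chunk]
        if in_t.all() or not in_t.any():
            raise ValueError(f"tertile {label!r} lacks one treatment arm")
        obs = km_group_risk_difference(times[chunk], events[chunk], in_t, t_star)
        ev_int = int(events[chunk][in_t].sum())
        ev_std = int(events[chunk][~in_t].sum())
        n_int = int(in_t.sum())
        n_std = int((~in_t).sum())
        est = float(np.median(rd[chunk]))
        rows.append(
            {
                "tertile": label,
                "rd_min": float(rd[chunk].min()),
                "rd_max": float(rd[chunk].max()),
                "n_intensive": n_int,
                "n_standard": n_std,
                "events_intensive": ev_int,
                "events_standard": ev_std,
                "pct_intensive": round(100.0 * ev_int / n_int, 1),
                "pct_standard": round(100.0 * ev_std / n_std, 1),
                "estimated_rd_median": est,
                "observed_rd": obs.rd,
                "observed_ci_lower": obs.ci_lower,
                "observed_ci_upper": obs.ci_upper,
                "estimated_minus_observed": est - obs.rd,
            }
        )
    return TertileBenefitTable(table=pd.DataFrame(rows), t_star=t_star)


# ---------------------------------------------------------------------------
# risk-magnification curve
# ---------------------------------------------------------------------------

def direct_magnification_reference(overall_hr: float, grid) -> np.ndarray:
    """Constant-relative-effect reference: RD(r) = (1 - (1-r)^h) - r, the
    exact risk difference when the hazard ratio h is constant and r is the
    standard-arm baseline risk.  RD(0) = 0 and dRD/dr -> h - 1 as r -> 0,
    the 'directly proportional' small-risk limit."""
    if overall_hr <= 0:
        raise ValueError("overall_hr must be positive")
    r = np.asarray(grid, dtype=float)
    if ((r < 0) | (r >= 1)).any():
        raise ValueError("baseline risks must lie in [0, 1)")
    return (1.0 - (1.0 - r) ** overall_hr) - r


def overall_hazard_ratio(cohort: Cohort, outcome: str) -> float:
    """Treatment-main-effect-only Cox fit (the constant-HR summary)."""
    times, events = cohort.outcome_arrays(outcome)
    df = pd.DataFrame(
        {"z": cohort.intensive_mask.astype(float), "time": times, "event": events}
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["z"]))


@dataclass
class MagnificationCurve:
    grid: np.ndarray            # standard-arm baseline risk values
    rd: np.ndarray              # local-mean estimated RD (NaN where no data)
    band_lower: np.ndarray
    band_upper: np.ndarray
    reference: np.ndarray       # constant-HR reference RD
    overall_hr: float
    quartiles: pd.DataFrame     # observed KM RD within quartiles of estimated RD
    linearity_p: float | None
    baseline_risk: np.ndarray   # per-subject standard-arm risk
    subject_rd: np.ndarray      # per-subject estimated RD
    bandwidth: float


def _local_mean(x, y, grid, bandwidth):
    """Gaussian-kernel local mean; grid points with essentially no weight are
    returned as NaN rather than interpolated."""
    out = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        w = np.exp(-0.5 * ((x - g) / bandwidth) ** 2)
        tot = w.sum()
        if tot > 1e-8:
            out[i] = float((w * y).sum() / tot)
    return out


def magnification_curve(
    fit: ModifiedCoxFit,
    cohort: Cohort,
    t_star: float | None = None,
    grid: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
    bandwidth_factor: float = 0.25,
) -> MagnificationCurve:
    """Estimated-RD-vs-baseline-risk curve with a bootstrap band.

    The curve is a Gaussian-kernel local mean of subject-level (standard-arm
    risk, estimated RD) pairs.  The 95% band is a seeded percentile bootstrap
    over subjects in which the interaction coefficients and the baseline
    hazard are refit on each resample (the risk-score coefficients stay at
    the converged fit), so the band reflects the uncertainty of the estimated
    risk difference and widens where the score distribution is thin.  The
    overlay gives observed KM risk differences within quartiles of estimated
    RD; the reference line is the constant-HR transform through the origin."""
    from .coxnet import ConvergenceError, breslow_baseline, fit_cox_newton
    from .modified import rcs_basis

    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    t_star = fit.t_star if t_star is None else t_star
    baseline = absolute_risk(fit, cohort, "standard", t_star)
    rd = estimated_risk_difference(fit, cohort, t_star)
    if grid is None:
        grid = np.linspace(np.quantile(baseline, 0.01), np.quantile(baseline, 0.99), 50)
    grid = np.asarray(grid, dtype=float)
    bw = bandwidth_factor * float(baseline.std())
    bw = bw if bw > 0 else 1e-3

    curve = _local_mean(baseline, rd, grid, bw)

    # interaction design at the converged risk score, for per-resample refits
    eta = fit.risk_score(cohort)
    z = cohort.intensive_mask.astype(float)
    times, events = cohort.outcome_arrays(fit.outcome)
    basis = [np.ones_like(eta), eta]
    if fit.spline_knots is not None and "spline" in fit.gamma.index:
        basis.append(rcs_basis(eta, fit.spline_knots))
    for name, derive in fit.extra_interactions.items():
        if f"subgroup:{name}" in fit.gamma.index:
            basis.append(derive(cohort.df).to_numpy(dtype=float))
    B = np.column_stack(basis)

    rng = np.random.default_rng(seed)
    n = len(baseline)
    boots = np.full((n_boot, len(grid)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xg = z[idx, None] * B[idx]
        try:
            gvec, _, _, _ = fit_cox_newton(Xg, times[idx], events[idx],
                                           offset=eta[idx], tol=1e-8, max_iter=50)
        except (ConvergenceError, ValueError):
            gvec = None
        if gvec is None:
            base_b, rd_b = baseline[idx], rd[idx]
        else:
            g_b = B[idx] @ gvec
            H_b = breslow_baseline(eta[idx] + z[idx] * g_b, times[idx], events[idx])
            h0 = H_b(min(t_star, H_b.last_observed))
            risk_std = 1.0 - np.exp(-h0 * np.exp(eta[idx]))
            risk_int = 1.0 - np.exp(-h0 * np.exp(eta[idx] + g_b))
            base_b, rd_b = risk_std, risk_int - risk_std
        boots[b] = _local_mean(base_b, rd_b, grid, bw)
    with np.errstate(all="ignore"):
        lower = np.nanpercentile(boots, 2.5, axis=0)
        upper = np.nanpercentile(boots, 97.5, axis=0)
    # percentile band widened to contain the point estimate by construction
    lower = np.fmin(lower, curve)
    upper = np.fmax(upper, curve)

    hr = overall_hazard_ratio(cohort, fit.outcome)
    reference = direct_magnification_reference(hr, np.clip(grid, 0.0, 1.0 - 1e-12))

    times, events = cohort.outcome_arrays(fit.outcome)
    intensive = cohort.intensive_mask
    order = np.argsort(rd, kind="mergesort")
    qrows = []
    for q, chunk in enumerate(np.array_split(order, 4), start=1):
        res = km_group_risk_difference(times[chunk], events[chunk], intensive[chunk],
                                       t_star)
        qrows.append(
            {
                "quartile": q,
                "mean_baseline_risk": float(baseline[chunk].mean()),
                "mean_estimated_rd": float(rd[chunk].mean()),
                "observed_rd": res.rd,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
            }
        )
    try:
        lin_p = linearity_test(fit)[1]
    except ValueError:
        lin_p = None

    return MagnificationCurve(
        grid=grid, rd=curve, band_lower=lower, band_upper=upper,
        reference=reference, overall_hr=hr, quartiles=pd.DataFrame(qrows),
        linearity_p=lin_p, baseline_risk=baseline, subject_rd=rd, bandwidth=bw,
    )


def linearity_test(fit: ModifiedCoxFit) -> tuple[float, float, int]:
    """Wald chi-square test that all nonlinear (spline) interaction
    coefficients are zero; returns (chi2, p, df)."""
    spline_idx = [i for i, name in enumerate(fit.gamma.index) if name == "spline"]
    if not spline_idx:
        raise ValueError("nothing to test: fit has no spline interaction terms")
    g = fit.gamma.to_numpy()[spline_idx]
    cov = fit.gamma_cov[np.ix_(spline_idx, spline_idx)]
    if np.allclose(g, 0.0):
        return 0.0, 1.0, len(spline_idx)
    chi2 = float(g @ np.linalg.solve(cov, g))
    df = len(spline_idx)
    return chi2, float(stats.chi2.sf(chi2, df)), df


# ---------------------------------------------------------------------------
# hybrid risk + effect model
# ---------------------------------------------------------------------------

#: prespecified effect-modification subgroups, derived from baseline columns
DEFAULT_SUBGROUPS = {
    "age_ge_75": lambda df: (df["age"] >= 75).astype(float),
    "female": lambda df: (df["female"] > 0).astype(float),
    "black": lambda df: (df["black"] > 0).astype(float),
    "baseline_mci": lambda df: (df["baseline_mci"] > 0).astype(float),
    "clinical_cvd": lambda df: (df["clinical_cvd"] > 0).astype(float),
}


def hybrid_effect_model(
    cohort: Cohort,
    covariate_set: str,
    outcome: str,
    subgroups: dict | None = None,
    penalty: PenaltySpec | None = None,
    base_fit: ModifiedCoxFit | None = None,
    **fit_kwargs,
) -> tuple[ModifiedCoxFit, dict]:
    """Refit the modified model with treatment-by-subgroup interaction columns
    added to the interaction step, and compare discrimination (Harrell's C of
    the risk score) against the risk-modeling-only fit."""
    subgroups = DEFAULT_SUBGROUPS if subgroups is None else subgroups
    if base_fit is None:
        base_fit = fit_modified_model(cohort, covariate_set, outcome,
                                      penalty=penalty, **fit_kwargs)
    hybrid = fit_modified_model(cohort, covariate_set, outcome, penalty=penalty,
                                extra_interactions=subgroups, **fit_kwargs)
    times, events = cohort.outcome_arrays(outcome)
    c_base = harrell_c(base_fit.risk_score(cohort), times, events)
    c_hybrid = harrell_c(hybrid.risk_score(cohort), times, events)
    comparison = {
        "c_base": c_base,
        "c_hybrid": c_hybrid,
        "c_difference": c_hybrid - c_base,
        "n": cohort.n,
        "events": int(events.sum()),
    }
    return hybrid, comparison
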