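"""Discrimination and calibration diagnostics for fixed-horizon survival risk.

Covers Harrell's concordance, decile calibration against Kaplan-Meier observed
risks (with the mean absolute error across deciles), the Greenwood-Nam-
D'Agostino chi-square calibration test, and the univariable standardized
hazard-ratio screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import stats

from .cohort import Cohort
from .survival import kaplan_meier, km_risk_at


def harrell_c(scores, times, events) -> float:
    """Harrell's C: among comparable pairs (earlier subject had the event),
    the fraction where the higher-scored subject failed first; score ties
    count one half.  0.5 is random ordering, 1 perfect."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    # lifelines orients concordance toward longer survival for higher values
    return float(concordance_index(times, -scores, events))


@dataclass
class CalibrationReport:
    """Per-group observed (KM) vs mean estimated risk at the horizon t_star.

    ``groups`` rows: n, events (by t_star), mean_estimated, observed,
    greenwood_var.  ``mae`` averages |observed - estimated| over groups.
    GND fields are filled by :func:`gnd_test`."""

    groups: pd.DataFrame
    mae: float
    t_star: float
    c_statistic: float | None = None
    gnd_chi2: float | None = None
    gnd_df: int | None = None
    gnd_p: float | None = None
    _times: np.ndarray = field(default=None, repr=False)
    _events: np.ndarray = field(default=None, repr=False)
    _group_idx: np.ndarray = field(default=None, repr=False)
    _estimated: np.ndarray = field(default=None, repr=False)


def decile_calibration(estimated_risks, times, events, t_star: float,
                       n_groups: int = 10) -> CalibrationReport:
    """Group subjects into near-equal deciles of estimated risk (stable order
    breaks ties) and compare the within-group KM observed risk at t_star with
    the mean estimated risk."""
    estimated_risks = np.asarray(estimated_risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(estimated_risks)
    if n < n_groups:
        raise ValueError("fewer subjects than calibration groups")
    order = np.argsort(estimated_risks, kind="mergesort")
    group_idx = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        if len(chunk) == 0:
            raise ValueError("empty calibration group")
        group_idx[chunk] = g
    rows = []
    for g in range(n_groups):
        mask = group_idx == g
        curve = kaplan_meier(times[mask], events[mask])
        obs, var = km_risk_at(curve, t_star, last_observed=float(times[mask].max()))
        rows.append(
            {
                "group": g + 1,
                "n": int(mask.sum()),
                "events": int(((events[mask] == 1) & (times[mask] <= t_star)).sum()),
                "mean_estimated": float(estimated_risks[mask].mean()),
                "observed": obs,
                "greenwood_var": var,
            }
        )
    groups = pd.DataFrame(rows)
    mae = float(np.abs(groups["observed"] - groups["mean_estimated"]).mean())
    return CalibrationReport(
        groups=groups,
        mae=mae,
        t_star=t_star,
        _times=times,
        _events=events,
        _group_idx=group_idx,
        _estimated=estimated_risks,
    )


def gnd_test(report: CalibrationReport, min_events: int = 5):
    """Greenwood-Nam-D'Agostino calibration test.

    chi2 = sum_g (O_g - E_g)^2 / V_g over retained groups, where O_g is the KM
    observed risk, E_g the mean model risk and V_g the Greenwood variance of
    O_g.  Groups with fewer than ``min_events`` events by t_star are merged
    into the adjacent (higher-risk) group before computation; df = retained
    groups - 1; p is the chi-square upper tail.  p > .05 reads as consistent
    with calibration.  Results are also written back onto the report."""
    if report._times is None:
        raise ValueError("report lacks subject-level data required by the GND test")
    times, events = report._times, report._events
    t_star = report.t_star
    # start from the original ordered grouping and merge forward
    n_groups = int(report._group_idx.max()) + 1
    memberships = [np.flatnonzero(report._group_idx == g) for g in range(n_groups)]

    def n_events(idx):
        return int(((events[idx] == 1) & (times[idx] <= t_star)).sum())

    merged = []
    carry = None
    for idx in memberships:
        idx = idx if carry is None else np.concatenate([carry, idx])
        if n_events(idx) < min_events:
            carry = idx
        else:
            merged.append(idx)
            carry = None
    if carry is not None:
        if merged:
            merged[-1] = np.concatenate([merged[-1], carry])
        else:
            merged = [carry]
    if len(merged) < 2:
        raise ValueError("insufficient groups after merging for the GND test")

    chi2 = 0.0
    for idx in merged:
        curve = kaplan_meier(times[idx], events[idx])
        obs, var = km_risk_at(curve, t_star, last_observed=float(times[idx].max()))
        est = float(report._estimated[idx].mean())
        if var <= 0:
            raise ValueError("zero Greenwood variance in a retained group")
        chi2 += (obs - est) ** 2 / var
    df = len(merged) - 1
    p = float(stats.chi2.sf(chi2, df))
    report.gnd_chi2 = float(chi2)
    report.gnd_df = df
    report.gnd_p = p
    return float(chi2), df, p


def standardized_univariate_hr(covariate, times, events) -> dict:
    """Single-covariate Cox fit with the covariate scaled to unit SD; returns
    the HR per 1-SD increase with its Wald 95% CI."""
    x = np.asarray(covariate, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("covariate has zero variance")
    df = pd.DataFrame({"x": (x - x.mean()) / sd, "time": times, "event": events})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return {
        "hr": float(np.exp(coef)),
        "ci_lower": float(np.exp(coef - 1.96 * se)),
        "ci_upper": float(np.exp(coef + 1.96 * se)),
        "log_hr": coef,
        "se": se,
    }


def univariate_hr_screen(cohort: Cohort, outcome: str,
                         covariates: list[str] | None = None) -> pd.DataFrame:
    """Standardized univariable HR of every covariate for one outcome,
    sorted by strength of association (the bar-plot screen)."""
    times, events = cohort.outcome_arrays(outcome)
    rows = []
    for name in covariates or cohort.covariate_names:
        x = cohort.df[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"covariate {name!r} has missing values; filter first")
        if x.std() == 0:
            continue
        res = standardized_univariate_hr(x, times, events)
        rows.append({"covariate": name, **res})
    out = pd.DataFrame(rows)
    return out.iloc[np.argsort(-np.abs(np.log(out["hr"])))].reset_index(drop=True)
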