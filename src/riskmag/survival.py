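"""Kaplan-Meier machinery: product-limit curves, Greenwood variance,
fixed-time risks and between-arm risk differences with normal CIs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import INTENSIVE


@dataclass
class SurvivalCurve:
    """Product-limit estimate: per distinct event time, the surviving fraction,
    its Greenwood variance, and risk-set/event counts.  At tied event/censor
    times events are counted first (censored subjects stay in the risk set)."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray


def kaplan_meier(times, events) -> SurvivalCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise ValueError("empty input")
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    d = events[order]
    n = len(t)
    grp_times, grp_start, grp_d = np.unique(t[d], return_index=True, return_counts=True)
    n_risk = n - np.searchsorted(t, grp_times, side="left")
    frac = 1.0 - grp_d / n_risk
    survival = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum( d / (n*(n-d)) )
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = grp_d / (n_risk * (n_risk - grp_d))
    incr = np.where(n_risk == grp_d, 0.0, incr)  # S hits 0; variance pinned at 0
    gw = survival**2 * np.cumsum(incr)
    return SurvivalCurve(
        event_times=grp_times,
        survival=survival,
        greenwood_var=gw,
        n_risk=n_risk,
        n_event=grp_d,
    )


def km_risk_at(curve: SurvivalCurve, t_star: float,
               last_observed: float | None = None) -> tuple[float, float]:
    """Risk 1 - S(t_star) and its Greenwood variance.

    If t_star lies beyond the last observed time the last step value is
    returned with a warning."""
    if t_star < 0:
        raise ValueError("t_star must be nonnegative")
    if last_observed is not None and t_star > last_observed:
        warnings.warn(
            f"t_star={t_star} beyond last observed time {last_observed}; "
            "returning the final step value",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.event_times, t_star, side="right") - 1
    if idx < 0:
        return 0.0, 0.0
    return float(1.0 - curve.survival[idx]), float(curve.greenwood_var[idx])


@dataclass
class RiskDifference:
    rd: float
    ci_lower: float
    ci_upper: float
    risk_intensive: float
    var_intensive: float
    risk_standard: float
    var_standard: float


def km_group_risk_difference(times, events, arm, t_star: float,
                             z: float = 1.959963984540054) -> RiskDifference:
    """Intensive-minus-standard KM risk difference at t_star, with a normal
    approximation CI on the plain risk scale: RD +/- z*sqrt(V_int + V_std)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    intensive = np.asarray(arm) == INTENSIVE if np.asarray(arm).dtype.kind in "UO" else np.asarray(arm, dtype=bool)
    if intensive.all() or (~intensive).all():
        raise ValueError("both arms must be present")
    out = {}
    for label, mask in (("intensive", intensive), ("standard", ~intensive)):
        curve = kaplan_meier(times[mask], events[mask])
        risk, var = km_risk_at(curve, t_star, last_observed=float(times[mask].max()))
        out[label] = (risk, var)
    rd = out["intensive"][0] - out["standard"][0]
    se = np.sqrt(out["intensive"][1] + out["standard"][1])
    return RiskDifference(
        rd=float(rd),
        ci_lower=float(rd - z * se),
        ci_upper=float(rd + z * se),
        risk_intensive=out["intensive"][0],
        var_intensive=out["intensive"][1],
        risk_standard=out["standard"][0],
        var_standard=out["standard"][1],
    )


def curve_table(curve: SurvivalCurve):
    """Tabular export (time, n_risk, n_event, survival, variance)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.event_times,
            "n_risk": curve.n_risk,
            "n_event": curve.n_event,
            "survival": curve.survival,
            "greenwood_var": curve.greenwood_var,
        }
    )
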