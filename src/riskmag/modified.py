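"""The modified elastic-net Cox model: joint baseline risk score and
treatment interaction, with absolute risks from a Breslow baseline hazard.

The hazard model is

    lambda(t | x, z) = lambda0(t) * exp( eta(x) + z * g(eta(x)) )

where eta = beta . x_std is the elastic-net-penalized risk score on
standardized covariates, z indicates the intensive arm, and
g(eta) = gamma_0 + gamma_1 * eta + gamma_2 * rcs(eta) is the treatment
log-hazard-ratio function (a constant relative effect plus linear and
optional restricted-cubic-spline dependence on the risk score; spline knots
at the 0.1/0.5/0.9 quantiles of eta).  Because treatment acts on the hazard
scale, the implied between-arm absolute risk difference tends to 0 as the
risk score tends to -inf for any bounded g — the zero-risk constraint is a
structural property of the risk transform, not a coefficient restriction.

Fitting alternates a penalized beta-step (interaction contribution held fixed
as an offset) with an unpenalized Newton gamma-step (eta held fixed as an
offset) until the risk score stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import INTENSIVE, Cohort
from .coxnet import (
    BreslowHazard,
    ConvergenceError,
    PenaltySpec,
    breslow_baseline,
    cox_information,
    fit_cox_newton,
    fit_elastic_net_cox,
)

#: name -> covariate list; None means "all covariates in the cohort".
#: The reduced sets approximate a point-of-care tiering: `basic_reduced`
#: holds 14 variables obtainable in a routine clinic encounter, while
#: `augmented_reduced` adds cognition testing, kidney labs and insurance.
DEFAULT_COVARIATE_SETS: dict[str, list[str] | None] = {
    "full": None,
    "augmented_reduced": [
        "age", "female", "black", "education", "current_smoker", "sbp", "dbp",
        "heart_rate", "bmi", "creatinine", "glucose", "clinical_cvd",
        "n_antihypertensive_medications", "statin",
        "moca", "logical_memory_i", "logical_memory_ii", "digit_symbol_coding",
        "serial_sevens", "employed", "medicare", "va_insurance", "egfr",
        "depression_history", "baseline_mci", "antidepressant",
    ],
    "basic_reduced": [
        "age", "female", "black", "education", "current_smoker", "sbp", "dbp",
        "heart_rate", "bmi", "creatinine", "glucose", "clinical_cvd",
        "n_antihypertensive_medications", "statin",
    ],
}


@dataclass
class DesignMatrix:
    X: np.ndarray          # standardized, one column per design column
    columns: list[str]
    standardization: pd.DataFrame  # per-column mean and sd of the raw design
    set_name: str


def select_covariate_set(cohort: Cohort, set_name: str,
                         covariate_sets: dict[str, list[str] | None] | None = None,
                         standardization: pd.DataFrame | None = None) -> DesignMatrix:
    """Build the standardized design for a named covariate set.

    Categorical covariates are one-hot expanded (first level dropped); every
    column is centered and scaled to unit SD and the transform recorded.  If
    ``standardization`` from a previous fit is given, it is applied instead of
    refitting the transform (for out-of-sample prediction)."""
    sets = covariate_sets or DEFAULT_COVARIATE_SETS
    if set_name not in sets:
        raise KeyError(f"unknown covariate set {set_name!r}")
    names = sets[set_name]
    names = list(cohort.covariate_names) if names is None else list(names)
    missing = [c for c in names if c not in cohort.df.columns]
    if missing:
        raise KeyError(f"covariates not in cohort: {missing}")

    pieces = {}
    for name in names:
        col = cohort.df[name].astype(float)
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values; filter first")
        if name in cohort.categorical:
            levels = np.sort(col.unique())
            for lev in levels[1:]:
                pieces[f"{name}={int(lev)}"] = (col == lev).astype(float)
        else:
            pieces[name] = col
    raw = pd.DataFrame(pieces)

    if standardization is None:
        mean = raw.mean()
        sd = raw.std(ddof=0)
        zero = sd.index[sd == 0].tolist()
        if zero:
            raise ValueError(f"zero-variance design column(s): {zero}")
        standardization = pd.DataFrame({"mean": mean, "sd": sd})
    else:
        standardization = standardization.loc[raw.columns]
    X = ((raw - standardization["mean"]) / standardization["sd"]).to_numpy(dtype=float)
    return DesignMatrix(X=X, columns=list(raw.columns),
                        standardization=standardization, set_name=set_name)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline nonlinear basis for 3 knots (one column),
    normalized by the squared knot span; linear in the tails."""
    k1, k2, k3 = knots
    if not (k1 < k2 < k3):
        raise ValueError("knots must be strictly increasing")

    def cub(u):
        return np.clip(u, 0.0, None) ** 3

    num = (
        cub(x - k1)
        - cub(x - k2) * (k3 - k1) / (k3 - k2)
        + cub(x - k3) * (k2 - k1) / (k3 - k2)
    )
    return num / (k3 - k1) ** 2


@dataclass
class ModifiedCoxFit:
    """Converged joint fit: risk-score coefficients, interaction coefficients
    with their covariance, spline knots, and the Breslow baseline hazard."""

    beta: pd.Series
    standardization: pd.DataFrame
    gamma: pd.Series
    gamma_cov: np.ndarray
    spline_knots: np.ndarray | None
    baseline_cumhaz: BreslowHazard
    covariate_set: str
    outcome: str
    t_star: float
    lambda_selected: float
    alpha: float
    n_iter: int
    final_rel_change: float
    converged: bool
    covariate_sets: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SETS))
    extra_interactions: dict = field(default_factory=dict)  # name -> callable(df)->0/1
    g_monotone: bool = True

    # -- prediction helpers -------------------------------------------------
    def design(self, cohort: Cohort) -> DesignMatrix:
        return select_covariate_set(cohort, self.covariate_set,
                                    covariate_sets=self.covariate_sets,
                                    standardization=self.standardization)

    def risk_score(self, cohort: Cohort) -> np.ndarray:
        """eta(x) per subject."""
        dm = self.design(cohort)
        return dm.X @ self.beta.loc[dm.columns].to_numpy()

    def interaction(self, eta: np.ndarray, cohort: Cohort | None = None) -> np.ndarray:
        """g(eta) per subject (plus any subgroup interaction terms)."""
        g = self.gamma.get("treat", 0.0) + self.gamma.get("eta", 0.0) * eta
        if self.spline_knots is not None and "spline" in self.gamma.index:
            g = g + self.gamma["spline"] * rcs_basis(eta, self.spline_knots)
        for name, derive in self.extra_interactions.items():
            key = f"subgroup:{name}"
            if key in self.gamma.index:
                if cohort is None:
                    raise ValueError("subgroup interactions require the cohort")
                g = g + self.gamma[key] * derive(cohort.df).to_numpy(dtype=float)
        return g


def _check_monotone(fit_gamma: pd.Series, knots, eta_range) -> bool:
    grid = np.linspace(eta_range[0], eta_range[1], 201)
    g = fit_gamma.get("treat", 0.0) + fit_gamma.get("eta", 0.0) * grid
    if knots is not None and "spline" in fit_gamma.index:
        g = g + fit_gamma["spline"] * rcs_basis(grid, knots)
    return bool(np.all(np.diff(grid + g) > 0))


def fit_modified_model(
    cohort: Cohort,
    covariate_set: str,
    outcome: str,
    penalty: PenaltySpec | None = None,
    interaction_basis: str = "linear+spline",
    covariate_sets: dict[str, list[str] | None] | None = None,
    extra_interactions: dict | None = None,
    t_star: float = 4.13,
    seed: int = 0,
    max_alternations: int = 20,
    rel_tol: float = 1e-6,
) -> ModifiedCoxFit:
    """Alternating fit of the modified elastic-net Cox model.

    (i) beta-step: elastic-net Cox for the risk score with the interaction
    contribution z*g(eta_prev) fixed as an offset; (ii) gamma-step: Newton
    Cox for the interaction coefficients with eta fixed as an offset.
    Alternation stops when the relative L2 change in eta falls below
    ``rel_tol`` or after ``max_alternations`` rounds.
    """
    penalty = penalty or PenaltySpec()
    if interaction_basis not in ("linear", "linear+spline"):
        raise ValueError(f"unknown interaction basis {interaction_basis!r}")
    times, events = cohort.outcome_arrays(outcome)
    z = cohort.intensive_mask.astype(float)
    if z.all() or not z.any():
        raise ValueError("both treatment arms must be present")
    if events.sum() < 30:
        raise ValueError("need at least 30 events to fit the modified model")

    dm = select_covariate_set(cohort, covariate_set, covariate_sets=covariate_sets)
    n = dm.X.shape[0]
    extra = dict(extra_interactions or {})
    extra_cols = {}
    for name, derive in list(extra.items()):
        col = derive(cohort.df).to_numpy(dtype=float)
        if len(np.unique(col)) < 2:
            import warnings

            warnings.warn(f"subgroup {name!r} has a single level; interaction dropped",
                          stacklevel=2)
            del extra[name]
        else:
            extra_cols[name] = col

    eta = np.zeros(n)
    offset_int = np.zeros(n)
    gamma = pd.Series(dtype=float)
    knots = None
    rel_change = np.inf
    enet = None
    scale = 1.0
    for it in range(1, max_alternations + 1):
        # (i) penalized risk-score step, interaction contribution fixed
        enet = fit_elastic_net_cox(dm.X, times, events, penalty,
                                   offset=offset_int, seed=seed)
        eta_new = dm.X @ enet.beta
        # calibration-slope refit: undo the scale compression the penalty
        # imposes on eta (direction and sparsity are kept from the penalized
        # step, the overall log-hazard slope is re-estimated unpenalized)
        if eta_new.std() > 0:
            s, _, _, _ = fit_cox_newton(eta_new[:, None], times, events,
                                        offset=offset_int)
            scale = float(s[0])
            eta_new = scale * eta_new
        rel_change = float(
            np.linalg.norm(eta_new - eta) / (np.linalg.norm(eta) + 1e-12)
        )
        eta = eta_new

        # (ii) interaction step given eta, offset = eta
        cols = {"treat": z, "eta": z * eta}
        if interaction_basis == "linear+spline":
            knots = np.quantile(eta, [0.1, 0.5, 0.9])
            if knots[0] < knots[1] < knots[2]:
                cols["spline"] = z * rcs_basis(eta, knots)
            else:  # degenerate score distribution: spline dropped
                knots = None
        for name, col in extra_cols.items():
            cols[f"subgroup:{name}"] = z * col
        Xg = np.column_stack(list(cols.values()))
        gvec, gcov, _, _ = fit_cox_newton(Xg, times, events, offset=eta)
        gamma = pd.Series(gvec, index=list(cols.keys()))
        gamma_cov = gcov
        offset_int = Xg @ gvec

        if rel_change < rel_tol:
            break
    converged = rel_change < rel_tol
    if not converged and it >= max_alternations:
        import warnings

        warnings.warn(
            f"alternation stopped at {max_alternations} rounds "
            f"(relative eta change {rel_change:.2e})",
            stacklevel=2,
        )

    lp = eta + offset_int
    base = breslow_baseline(lp, times, events)
    fit = ModifiedCoxFit(
        beta=pd.Series(scale * enet.beta, index=dm.columns),
        standardization=dm.standardization,
        gamma=gamma,
        gamma_cov=gamma_cov,
        spline_knots=knots,
        baseline_cumhaz=base,
        covariate_set=covariate_set,
        outcome=outcome,
        t_star=t_star,
        lambda_selected=enet.lam,
        alpha=penalty.alpha,
        n_iter=it,
        final_rel_change=rel_change,
        converged=converged,
        covariate_sets=dict(covariate_sets or DEFAULT_COVARIATE_SETS),
        extra_interactions=extra,
    )
    fit.g_monotone = _check_monotone(gamma, knots, (eta.min(), eta.max()))
    return fit


# ---------------------------------------------------------------------------
# absolute risks and risk differences under a fit
# ---------------------------------------------------------------------------

def risk_from_score(fit: ModifiedCoxFit, eta, arm: str, t_star: float | None = None,
                    cohort: Cohort | None = None):
    """Absolute risk 1 - exp(-H0(t*) * exp(eta + z*g(eta))) at score eta."""
    t_star = fit.t_star if t_star is None else t_star
    if t_star > fit.baseline_cumhaz.last_observed:
        raise ValueError(
            f"t_star={t_star} beyond last observed time "
            f"{fit.baseline_cumhaz.last_observed}"
        )
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    z = 1.0 if arm == INTENSIVE else 0.0
    lp = eta + z * fit.interaction(eta, cohort)
    h0 = fit.baseline_cumhaz(t_star)
    risk = 1.0 - np.exp(-h0 * np.exp(lp))
    return risk


def absolute_risk(fit: ModifiedCoxFit, cohort: Cohort, arm: str,
                  t_star: float | None = None) -> np.ndarray:
    """Per-subject absolute risk by t_star if assigned to ``arm``."""
    eta = fit.risk_score(cohort)
    return risk_from_score(fit, eta, arm, t_star, cohort=cohort)


def estimated_risk_difference(fit: ModifiedCoxFit, cohort: Cohort,
                              t_star: float | None = None) -> np.ndarray:
    """Per-subject intensive-minus-standard model risk difference
    (negative = benefit)."""
    return absolute_risk(fit, cohort, INTENSIVE, t_star) - absolute_risk(
        fit, cohort, "standard", t_star
    )
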