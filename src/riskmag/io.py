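"""Text-file interfaces: cohort CSV round-trips, fit and config serialization.

Cohorts are plain comma-separated files with a header (id, arm, has_followup,
per-outcome time/event columns, covariates); absent covariate values are empty
fields.  Fits and configurations serialize to structured text (JSON / YAML).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import INTENSIVE, STANDARD, Cohort
from .coxnet import BreslowHazard
from .modified import ModifiedCoxFit


def write_cohort(cohort: Cohort, path) -> None:
    path = Path(path)
    df = cohort.df.copy()
    meta = {
        "covariates": list(cohort.covariate_names),
        "outcomes": list(cohort.outcome_names),
        "categorical": list(cohort.categorical),
    }
    with open(path, "w") as fh:
        fh.write("#riskmag-cohort " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)


def read_cohort(path) -> Cohort:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#riskmag-cohort "):
            raise ValueError(f"{path}: missing cohort header line")
        meta = json.loads(header[len("#riskmag-cohort "):])
        df = pd.read_csv(fh)
    required = ["id", "arm", "has_followup"]
    for outcome in meta["outcomes"]:
        required += [f"time_{outcome}", f"event_{outcome}"]
    missing = [c for c in required + meta["covariates"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_arm = ~df["arm"].isin([INTENSIVE, STANDARD])
    if bad_arm.any():
        raise ValueError(f"{path}: bad arm value at data line {int(np.flatnonzero(bad_arm)[0]) + 1}")
    for outcome in meta["outcomes"]:
        ev = df[f"event_{outcome}"]
        if not ev.isin([0, 1]).all():
            line = int(np.flatnonzero(~ev.isin([0, 1]))[0]) + 1
            raise ValueError(f"{path}: event_{outcome} outside {{0,1}} at data line {line}")
        t = df[f"time_{outcome}"]
        if (t <= 0).any() or t.isna().any():
            line = int(np.flatnonzero((t <= 0) | t.isna())[0]) + 1
            raise ValueError(f"{path}: nonpositive time_{outcome} at data line {line}")
    return Cohort(
        df=df,
        covariate_names=meta["covariates"],
        outcome_names=meta["outcomes"],
        categorical=meta["categorical"],
    )


def write_fit(fit: ModifiedCoxFit, path) -> None:
    """Serialize coefficients, standardization, baseline hazard and metadata.

    Subgroup-interaction callables are not serializable; their names are kept
    so a reloaded fit can predict when re-attached to the same definitions."""
    payload = {
        "outcome": fit.outcome,
        "covariate_set": fit.covariate_set,
        "t_star": fit.t_star,
        "lambda": fit.lambda_selected,
        "alpha": fit.alpha,
        "n_iter": fit.n_iter,
        "final_rel_change": fit.final_rel_change,
        "converged": fit.converged,
        "g_monotone": fit.g_monotone,
        "beta": {k: float(v) for k, v in fit.beta.items()},
        "standardization": {
            k: {"mean": float(r["mean"]), "sd": float(r["sd"])}
            for k, r in fit.standardization.iterrows()
        },
        "gamma": {k: float(v) for k, v in fit.gamma.items()},
        "gamma_cov": np.asarray(fit.gamma_cov).tolist(),
        "spline_knots": None if fit.spline_knots is None else list(map(float, fit.spline_knots)),
        "baseline_cumhaz": {
            "times": fit.baseline_cumhaz.times.tolist(),
            "cumhaz": fit.baseline_cumhaz.cumhaz.tolist(),
            "last_observed": fit.baseline_cumhaz.last_observed,
        },
        "covariate_sets": fit.covariate_sets,
        "extra_interaction_names": list(fit.extra_interactions),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_fit(path) -> ModifiedCoxFit:
    payload = json.loads(Path(path).read_text())
    std = pd.DataFrame(payload["standardization"]).T[["mean", "sd"]]
    base = payload["baseline_cumhaz"]
    return ModifiedCoxFit(
        beta=pd.Series(payload["beta"]),
        standardization=std,
        gamma=pd.Series(payload["gamma"]),
        gamma_cov=np.asarray(payload["gamma_cov"], dtype=float),
        spline_knots=None if payload["spline_knots"] is None else np.asarray(payload["spline_knots"]),
        baseline_cumhaz=BreslowHazard(
            times=np.asarray(base["times"], dtype=float),
            cumhaz=np.asarray(base["cumhaz"], dtype=float),
            last_observed=base["last_observed"],
        ),
        covariate_set=payload["covariate_set"],
        outcome=payload["outcome"],
        t_star=payload["t_star"],
        lambda_selected=payload["lambda"],
        alpha=payload["alpha"],
        n_iter=payload["n_iter"],
        final_rel_change=payload["final_rel_change"],
        converged=payload["converged"],
        covariate_sets=payload["covariate_sets"],
        g_monotone=payload["g_monotone"],
    )


def dump_yaml(obj, path) -> None:
    def clean(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: clean(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    Path(path).write_text(yaml.safe_dump(clean(obj), sort_keys=True))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())
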