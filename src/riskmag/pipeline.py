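"""End-to-end orchestration: simulate or load a cohort, filter, then for every
(outcome, covariate set) combination fit the modified model, evaluate
calibration/discrimination, build the tertile benefit table and the
risk-magnification curve, and run the hybrid risk+effect comparison."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reporting
from .cohort import (
    DEFAULT_OUTCOMES,
    Cohort,
    CohortConfig,
    OutcomeDefinition,
    TruthParameters,
    apply_eligibility_filter,
    simulate_cohort,
)
from .coxnet import PenaltySpec
from .evaluation import decile_calibration, gnd_test, harrell_c
from .io import dump_yaml, read_cohort, write_cohort, write_fit
from .magnification import (
    hybrid_effect_model,
    magnification_curve,
    tertile_benefit_table,
)
from .modified import DEFAULT_COVARIATE_SETS, absolute_risk, fit_modified_model

log = logging.getLogger("riskmag")


@dataclass
class PipelineConfig:
    """Configuration for a replication run.

    ``input_path`` of None means simulate; otherwise a cohort CSV is loaded.
    All randomness flows from the three named seeds."""

    input_path: str | None = None
    n_subjects: int = 7918
    t_star: float = 4.13
    outcomes: tuple = DEFAULT_OUTCOMES
    covariate_sets: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SETS))
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    interaction_basis: str = "linear+spline"
    n_boot: int = 200
    run_hybrid: bool = True
    seed_simulation: int = 1
    seed_cv: int = 2
    seed_bootstrap: int = 3
    output_dir: str = "riskmag_out"

    def validate(self, cohort: Cohort | None = None) -> None:
        if self.t_star <= 0:
            raise ValueError("t_star must be positive")
        if cohort is not None:
            for name, cols in self.covariate_sets.items():
                for c in cols or []:
                    if c not in cohort.covariate_names:
                        raise ValueError(f"covariate set {name!r} references missing covariate {c!r}")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (OutcomeDefinition, PenaltySpec)):
                return vars(o) if not isinstance(o, OutcomeDefinition) else {
                    "name": o.name, "components": list(o.components)
                }
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(vars(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ComboResult:
    outcome: str
    covariate_set: str
    fit: object = None
    calibration: object = None
    tertiles: object = None
    curve: object = None
    hybrid_comparison: dict | None = None
    failed: bool = False
    failure_reason: str = ""
    seconds: float = 0.0


@dataclass
class RunReport:
    config_hash: str
    seeds: dict
    cohort_tally: dict
    results: dict  # (outcome, set) -> ComboResult


def _analysis_cohort(config: PipelineConfig) -> tuple[Cohort, dict]:
    if config.input_path is None:
        cc = CohortConfig(n_subjects=config.n_subjects, seed=config.seed_simulation)
        cohort = simulate_cohort(cc, outcome_defs=tuple(config.outcomes))
    else:
        cohort = read_cohort(config.input_path)
    cohort, tally = apply_eligibility_filter(cohort)
    return cohort, tally


def run_combination(cohort: Cohort, config: PipelineConfig, outcome: str,
                    set_name: str) -> ComboResult:
    res = ComboResult(outcome=outcome, covariate_set=set_name)
    t0 = time.time()
    try:
        fit = fit_modified_model(
            cohort, set_name, outcome, penalty=config.penalty,
            interaction_basis=config.interaction_basis,
            covariate_sets=config.covariate_sets,
            t_star=config.t_star, seed=config.seed_cv,
        )
        times, events = cohort.outcome_arrays(outcome)
        # overall risk averaged over the randomized arms, per the pooled-score design
        risks = 0.5 * (
            absolute_risk(fit, cohort, "intensive", config.t_star)
            + absolute_risk(fit, cohort, "standard", config.t_star)
        )
        report = decile_calibration(risks, times, events, config.t_star)
        gnd_test(report)
        report.c_statistic = harrell_c(fit.risk_score(cohort), times, events)
        res.fit = fit
        res.calibration = report
        res.tertiles = tertile_benefit_table(fit, cohort, config.t_star)
        res.curve = magnification_curve(
            fit, cohort, config.t_star, n_boot=config.n_boot,
            seed=config.seed_bootstrap,
        )
        if config.run_hybrid:
            _, comparison = hybrid_effect_model(
                cohort, set_name, outcome, penalty=config.penalty,
                base_fit=fit, covariate_sets=config.covariate_sets,
                interaction_basis=config.interaction_basis,
                t_star=config.t_star, seed=config.seed_cv,
            )
            res.hybrid_comparison = comparison
    except Exception as err:  # failures isolate per combination
        res.failed = True
        res.failure_reason = f"{type(err).__name__}: {err}"
        log.warning("combination (%s, %s) failed: %s\n%s", outcome, set_name, err,
                    traceback.format_exc())
    res.seconds = time.time() - t0
    return res


def run_pipeline(config: PipelineConfig) -> RunReport:
    cohort, tally = _analysis_cohort(config)
    config.validate(cohort)
    results = {}
    for od in config.outcomes:
        outcome = od.name if isinstance(od, OutcomeDefinition) else str(od)
        for set_name in config.covariate_sets:
            log.info("fitting outcome=%s set=%s", outcome, set_name)
            results[(outcome, set_name)] = run_combination(cohort, config, outcome,
                                                           set_name)
    return RunReport(
        config_hash=config.config_hash(),
        seeds={
            "simulation": config.seed_simulation,
            "cv": config.seed_cv,
            "bootstrap": config.seed_bootstrap,
        },
        cohort_tally=tally,
        results=results,
    )


def render_report(report: RunReport, outdir) -> list[Path]:
    """Write tables, figures and a summary index for a completed run."""
    from .plots import calibration_plot, magnification_plot

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    summary_rows = []
    for (outcome, set_name), res in report.results.items():
        stem = f"{outcome}__{set_name}"
        if res.failed:
            (outdir / f"{stem}.FAILED.txt").write_text(res.failure_reason + "\n")
            written.append(outdir / f"{stem}.FAILED.txt")
            summary_rows.append({"outcome": outcome, "covariate_set": set_name,
                                 "failed": True, "reason": res.failure_reason})
            continue
        write_fit(res.fit, outdir / f"{stem}.fit.json")
        res.calibration.groups.to_csv(outdir / f"{stem}.calibration.csv", index=False)
        tt = res.tertiles.table.copy()
        tt["events_prevented_per_1000"] = [
            reporting.events_prevented_per_1000(v) for v in tt["estimated_rd_median"]
        ]
        tt.to_csv(outdir / f"{stem}.tertiles.csv", index=False)
        pd.DataFrame(
            {
                "baseline_risk": res.curve.grid,
                "estimated_rd": res.curve.rd,
                "band_lower": res.curve.band_lower,
                "band_upper": res.curve.band_upper,
                "reference_rd": res.curve.reference,
            }
        ).to_csv(outdir / f"{stem}.curve.csv", index=False)
        calibration_plot(res.calibration, outdir / f"{stem}.calibration.png",
                         title=f"{outcome} / {set_name}")
        magnification_plot(res.curve, outdir / f"{stem}.magnification.png",
                           title=f"{outcome} / {set_name}")
        row = {
            "outcome": outcome,
            "covariate_set": set_name,
            "failed": False,
            "c_statistic": res.calibration.c_statistic,
            "mae": res.calibration.mae,
            "gnd_p": res.calibration.gnd_p,
            "linearity_p": res.curve.linearity_p,
            "overall_hr": res.curve.overall_hr,
            "high_tertile_estimated_rd": float(
                res.tertiles.table["estimated_rd_median"].iloc[0]
            ),
            "high_tertile_est_minus_obs": reporting.estimated_minus_observed(
                float(res.tertiles.table["estimated_rd_median"].iloc[0]),
                float(res.tertiles.table["observed_rd"].iloc[0]),
            ),
        }
        if res.hybrid_comparison:
            row["c_hybrid"] = res.hybrid_comparison["c_hybrid"]
            row["c_difference"] = res.hybrid_comparison["c_difference"]
        summary_rows.append(row)
        written += [outdir / f"{stem}{suffix}" for suffix in
                    (".fit.json", ".calibration.csv", ".tertiles.csv", ".curve.csv",
                     ".calibration.png", ".magnification.png")]
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    dump_yaml({"config_hash": report.config_hash, "seeds": report.seeds,
               "cohort": report.cohort_tally}, outdir / "provenance.yaml")
    written += [outdir / "summary.csv", outdir / "provenance.yaml"]
    return written
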