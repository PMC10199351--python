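import numpy as np
import pandas as pd
import pytest

from riskmag.cohort import (
    DEFAULT_OUTCOMES,
    CohortConfig,
    CovariateSpec,
    OutcomeDefinition,
    TruthParameters,
    apply_eligibility_filter,
    generate_covariates,
    generate_outcomes,
    oracle_absolute_risk,
    oracle_risk_difference,
    simulate_cohort,
)
from riskmag.survival import kaplan_meier, km_risk_at


class TestGenerateCovariates:
    def test_binary_prevalence_matches_spec(self):
        cfg = CohortConfig(n_subjects=100_000, seed=0)
        cov, _ = generate_covariates(cfg)
        assert abs(cov["female"].mean() - 0.351) < 0.01
        assert abs(cov["black"].mean() - 0.311) < 0.01

    def test_continuous_marginals(self):
        cfg = CohortConfig(n_subjects=100_000, seed=0)
        cov, _ = generate_covariates(cfg)
        assert abs(cov["age"].mean() - 67.9) < 0.15
        assert abs(cov["age"].std() - 9.3) < 0.15

    def test_categorical_level_probabilities(self):
        cfg = CohortConfig(n_subjects=100_000, seed=0)
        cov, _ = generate_covariates(cfg)
        frac = cov["education"].value_counts(normalize=True).sort_index()
        assert np.allclose(frac.to_numpy(), [0.088, 0.163, 0.355, 0.394], atol=0.01)

    def test_identity_correlation_gives_independence(self):
        cfg = CohortConfig(n_subjects=40_000, seed=1)
        cov, _ = generate_covariates(cfg)
        r = np.corrcoef(cov["female"], cov["black"])[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_subjects)

    def test_requested_correlation_is_induced(self):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = 0.6
        specs = [
            CovariateSpec("u", "continuous", mean=0, sd=1),
            CovariateSpec("v", "continuous", mean=0, sd=1),
        ]
        cfg = CohortConfig(n_subjects=50_000, covariate_specs=specs, correlation=corr, seed=2)
        cov, _ = generate_covariates(cfg)
        assert abs(np.corrcoef(cov["u"], cov["v"])[0, 1] - 0.6) < 0.02

    def test_determinism_same_seed(self):
        cfg = CohortConfig(n_subjects=500, seed=7)
        a, arm_a = generate_covariates(cfg)
        b, arm_b = generate_covariates(CohortConfig(n_subjects=500, seed=7))
        pd.testing.assert_frame_equal(a, b)
        assert (arm_a == arm_b).all()

    def test_randomization_independent_of_covariates(self):
        cfg = CohortConfig(n_subjects=50_000, seed=3)
        cov, arm = generate_covariates(cfg)
        z = (arm == "intensive").astype(float)
        for name in ("age", "female", "moca"):
            r = np.corrcoef(cov[name], z)[0, 1]
            assert abs(r) < 3 / np.sqrt(cfg.n_subjects)

    def test_non_psd_correlation_rejected(self):
        corr = np.array([[1.0, 2.0], [2.0, 1.0]])
        specs = [
            CovariateSpec("u", "continuous", mean=0, sd=1),
            CovariateSpec("v", "continuous", mean=0, sd=1),
        ]
        cfg = CohortConfig(n_subjects=100, covariate_specs=specs, correlation=corr)
        with pytest.raises(ValueError, match="positive semidefinite"):
            generate_covariates(cfg)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CovariateSpec("bad", "binary", prevalence=1.5).validate()
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)


class TestGenerateOutcomes:
    def test_homogeneous_null_matches_closed_form(self):
        # beta=0, theta=0: 4-year composite risk is 1 - exp(-4 * lam_total)
        truth = TruthParameters(
            beta={},
            effect_params={"log_hr": 0.0},
            component_base_rates={"amci": 0.03, "any_mci": 0.01, "dementia": 0.01, "death": 0.01},
            component_loadings={"amci": 1, "any_mci": 1, "dementia": 1, "death": 1},
            censor_window=(4.5, 6.0),
        )
        cfg = CohortConfig(n_subjects=100_000, n_covariates=2, seed=5)
        co = simulate_cohort(cfg, truth, outcome_defs=(DEFAULT_OUTCOMES[0],))
        t, e = co.outcome_arrays("pd_amci")
        curve = kaplan_meier(t, e)
        risk, var = km_risk_at(curve, 4.0)
        expected = 1 - np.exp(-4 * 0.04)
        assert abs(risk - expected) < max(3 * np.sqrt(var), 0.005)

    def test_composite_nesting(self, midsize_cohort):
        # adding components can only shorten the composite event time
        df = midsize_cohort.df
        assert (df["time_pd_amci_death"] <= df["time_pd_amci"] + 1e-12).all()
        assert (df["time_pd_mci_death"] <= df["time_pd_death"] + 1e-12).all()

    def test_event_fractions_emulate_trial(self, default_truth):
        co = simulate_cohort(CohortConfig(n_subjects=50_000, seed=21), default_truth)
        m = co.intensive_mask
        t, e = co.outcome_arrays("pd_amci")
        assert 0.17 < e[m].mean() < 0.21     # intensive arm, ~765/3989
        assert 0.19 < e[~m].mean() < 0.23    # standard arm, ~828/3929

    def test_unknown_effect_kind_fails(self):
        with pytest.raises(ValueError, match="effect_kind"):
            TruthParameters(effect_kind="quadratic")

    def test_unknown_component_fails(self):
        with pytest.raises(ValueError, match="unknown components"):
            OutcomeDefinition("bad", ("stroke",))

    def test_simulation_deterministic(self, default_truth):
        a = simulate_cohort(CohortConfig(n_subjects=400, seed=13), default_truth)
        b = simulate_cohort(CohortConfig(n_subjects=400, seed=13), default_truth)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestEligibilityFilter:
    def test_no_flags_no_exclusions(self, midsize_cohort):
        filtered, tally = apply_eligibility_filter(midsize_cohort)
        assert tally["no_followup"] == 0
        assert tally["missing_covariates"] == 0
        assert filtered.n == midsize_cohort.n

    def test_followup_exclusion_fraction(self, default_truth):
        # 643 of 9631 randomized flagged without follow-up -> 6.7%
        co = simulate_cohort(CohortConfig(n_subjects=9631, seed=17), default_truth)
        co.df.loc[: 642, "has_followup"] = 0
        _, tally = apply_eligibility_filter(co)
        assert tally["no_followup"] == 643
        assert tally["no_followup_pct"] == 6.7

    def test_single_missing_covariate_removed(self, default_truth):
        co = simulate_cohort(CohortConfig(n_subjects=200, seed=19), default_truth)
        co.df.loc[5, "age"] = np.nan
        filtered, tally = apply_eligibility_filter(co)
        assert tally["missing_covariates"] == 1
        assert filtered.n == 199
        assert 5 not in filtered.df["id"].to_numpy()

    def test_empty_result_fails(self, default_truth):
        co = simulate_cohort(CohortConfig(n_subjects=50, seed=23), default_truth)
        co.df["has_followup"] = 0
        with pytest.raises(ValueError, match="every subject"):
            apply_eligibility_filter(co)


class TestOracles:
    def test_risk_vanishes_at_time_zero(self, default_truth):
        assert oracle_absolute_risk(default_truth, 0.5, "standard", 0.0) == 0.0

    def test_closed_form_value(self):
        truth = TruthParameters(
            beta={},
            effect_params={"log_hr": 0.0},
            component_base_rates={"amci": 0.04, "any_mci": 0.01, "dementia": 0.01, "death": 0.01},
            component_loadings={"amci": 1, "any_mci": 1, "dementia": 1, "death": 1},
        )
        # total composite rate 0.05/y at eta=0 -> risk(4.13) = 1 - exp(-0.2065)
        r = oracle_absolute_risk(truth, 0.0, "standard", 4.13)
        assert abs(r - (1 - np.exp(-0.2065))) < 1e-12

    def test_risk_nondecreasing_in_time(self, default_truth):
        ts = np.linspace(0.1, 8, 40)
        risks = [oracle_absolute_risk(default_truth, 0.3, "intensive", t) for t in ts]
        assert np.all(np.diff(risks) > 0)

    def test_oracle_matches_km_simulation(self, default_truth):
        cfg = CohortConfig(n_subjects=100_000, arm_ratio=0.0, seed=29)
        co = simulate_cohort(cfg, default_truth, outcome_defs=(DEFAULT_OUTCOMES[0],))
        sub = co.df[np.abs(co.df["truth_eta"]) < 0.05]
        t = sub["time_pd_amci"].to_numpy()
        e = sub["event_pd_amci"].to_numpy()
        risk, var = km_risk_at(kaplan_meier(t, e), 4.13)
        expected = oracle_absolute_risk(default_truth, 0.0, "standard", 4.13)
        assert abs(risk - expected) < max(3 * np.sqrt(var), 0.005)

    def test_null_effect_gives_zero_rd(self):
        truth = TruthParameters(effect_params={"log_hr": 0.0})
        for eta in (-1.0, 0.0, 1.5):
            assert oracle_risk_difference(truth, eta, 4.13) == pytest.approx(0.0, abs=1e-15)

    def test_constant_hr_survival_power_identity(self, default_truth):
        eta = 0.4
        r = oracle_absolute_risk(default_truth, eta, "standard", 4.13)
        h = 0.85
        rd = oracle_risk_difference(default_truth, eta, 4.13)
        assert rd == pytest.approx((1 - (1 - r) ** h) - r, abs=1e-12)

    def test_zero_risk_limit(self, default_truth):
        assert abs(oracle_risk_difference(default_truth, -10.0, 4.13)) < 1e-3
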