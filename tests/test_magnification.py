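import numpy as np
import pandas as pd
import pytest

from conftest import two_arm_exponential
from riskmag.cohort import (
    CohortConfig,
    TruthParameters,
    linear_in_risk_truth,
    simulate_cohort,
)
from riskmag.coxnet import PenaltySpec
from riskmag.magnification import (
    DEFAULT_SUBGROUPS,
    direct_magnification_reference,
    hybrid_effect_model,
    linearity_test,
    magnification_curve,
    overall_hazard_ratio,
    tertile_benefit_table,
)
from riskmag.modified import fit_modified_model
from riskmag.survival import kaplan_meier, km_risk_at

FAST_PENALTY = PenaltySpec(alpha=0.5, lam=0.01)


class TestDirectReference:
    def test_null_hr_gives_zero(self):
        grid = np.linspace(0, 0.9, 10)
        assert np.allclose(direct_magnification_reference(1.0, grid), 0.0)

    def test_origin_and_small_risk_slope(self):
        h = 0.85
        assert direct_magnification_reference(h, [0.0])[0] == 0.0
        r = 1e-7
        slope = direct_magnification_reference(h, [r])[0] / r
        assert slope == pytest.approx(h - 1, abs=1e-6)

    def test_sign_and_interior_maximum(self):
        grid = np.linspace(0.001, 0.999, 999)
        rd = direct_magnification_reference(0.85, grid)
        assert np.all(rd < 0)
        peak = np.argmax(np.abs(rd))
        assert 0 < peak < len(grid) - 1
        assert np.all(direct_magnification_reference(1.3, grid) > 0)

    def test_identity_matches_two_arm_simulation(self):
        # h=0.85, standard-arm risk 0.2 at t*: direct simulation oracle
        t_star = 4.0
        rate = -np.log(0.8) / t_star  # standard-arm risk exactly 0.2
        times, events, z = two_arm_exponential(200_000, rate, 0.85, seed=301,
                                               censor=(5.0, 6.0))
        r_int, _ = km_risk_at(kaplan_meier(times[z], events[z]), t_star)
        r_std, _ = km_risk_at(kaplan_meier(times[~z], events[~z]), t_star)
        expected = direct_magnification_reference(0.85, [0.2])[0]
        assert (r_int - r_std) == pytest.approx(expected, abs=0.005)
        assert expected == pytest.approx((1 - 0.8**0.85) - 0.2, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            direct_magnification_reference(0.0, [0.1])
        with pytest.raises(ValueError):
            direct_magnification_reference(0.85, [1.0])


class TestTertileTable:
    def test_counts_partition_cohort(self, midsize_fit, midsize_cohort):
        tab = tertile_benefit_table(midsize_fit, midsize_cohort).table
        m = midsize_cohort.intensive_mask
        assert tab["n_intensive"].sum() == m.sum()
        assert tab["n_standard"].sum() == (~m).sum()
        sizes = (tab["n_intensive"] + tab["n_standard"]).to_numpy()
        assert sizes.max() - sizes.min() <= 1

    def test_percentages_consistent(self, midsize_fit, midsize_cohort):
        tab = tertile_benefit_table(midsize_fit, midsize_cohort).table
        for _, row in tab.iterrows():
            assert row["pct_intensive"] == round(
                100.0 * row["events_intensive"] / row["n_intensive"], 1
            )

    def test_estimated_minus_observed_definition(self, midsize_fit, midsize_cohort):
        tab = tertile_benefit_table(midsize_fit, midsize_cohort).table
        np.testing.assert_allclose(
            tab["estimated_minus_observed"],
            tab["estimated_rd_median"] - tab["observed_rd"],
        )

    def test_null_effect_observed_rds_near_zero(self):
        truth = TruthParameters(effect_params={"log_hr": 0.0})
        co = simulate_cohort(CohortConfig(n_subjects=6000, seed=303), truth)
        fit = fit_modified_model(co, "full", "pd_amci", penalty=FAST_PENALTY)
        tab = tertile_benefit_table(fit, co).table
        for _, row in tab.iterrows():
            halfwidth = (row["observed_ci_upper"] - row["observed_ci_lower"]) / 2
            assert abs(row["observed_rd"]) < 3.5 / 1.96 * halfwidth


class TestMagnificationCurve:
    def test_band_contains_estimate_and_is_deterministic(self, midsize_fit, midsize_cohort):
        a = magnification_curve(midsize_fit, midsize_cohort, n_boot=40, seed=9)
        b = magnification_curve(midsize_fit, midsize_cohort, n_boot=40, seed=9)
        valid = ~np.isnan(a.rd)
        assert np.all(a.band_lower[valid] <= a.rd[valid] + 1e-12)
        assert np.all(a.band_upper[valid] >= a.rd[valid] - 1e-12)
        np.testing.assert_array_equal(a.band_lower, b.band_lower)
        np.testing.assert_array_equal(a.band_upper, b.band_upper)

    def test_constant_hr_truth_tracks_reference(self, midsize_fit, midsize_cohort):
        cur = magnification_curve(midsize_fit, midsize_cohort, n_boot=60, seed=11)
        lo = np.quantile(cur.baseline_risk, 0.15)
        hi = np.quantile(cur.baseline_risk, 0.85)
        sel = (cur.grid >= lo) & (cur.grid <= hi) & ~np.isnan(cur.rd)
        width = cur.band_upper[sel] - cur.band_lower[sel]
        assert np.all(np.abs(cur.rd[sel] - cur.reference[sel]) <= width + 0.01)

    def test_null_effect_curve_near_zero(self):
        truth = TruthParameters(effect_params={"log_hr": 0.0})
        co = simulate_cohort(CohortConfig(n_subjects=6000, seed=305), truth)
        fit = fit_modified_model(co, "full", "pd_amci", penalty=FAST_PENALTY)
        cur = magnification_curve(fit, co, n_boot=60, seed=13)
        valid = ~np.isnan(cur.rd)
        covers = (cur.band_lower[valid] - 0.01 <= 0) & (cur.band_upper[valid] + 0.01 >= 0)
        assert covers.mean() > 0.9

    def test_band_shrinks_with_n(self, default_truth):
        widths = []
        for n, seed in ((2000, 307), (8000, 309)):
            co = simulate_cohort(CohortConfig(n_subjects=n, seed=seed), default_truth)
            fit = fit_modified_model(co, "basic_reduced", "pd_amci", penalty=FAST_PENALTY)
            cur = magnification_curve(fit, co, n_boot=60, seed=15)
            sel = (cur.grid >= np.quantile(cur.baseline_risk, 0.2)) & (
                cur.grid <= np.quantile(cur.baseline_risk, 0.8)
            )
            widths.append(np.nanmean(cur.band_upper[sel] - cur.band_lower[sel]))
        assert widths[1] < widths[0]

    def test_overall_hr_recovered(self, midsize_cohort):
        hr = overall_hazard_ratio(midsize_cohort, "pd_amci")
        assert 0.72 < hr < 0.99  # truth applies HR 0.85 at every risk level

    def test_invalid_n_boot(self, midsize_fit, midsize_cohort):
        with pytest.raises(ValueError):
            magnification_curve(midsize_fit, midsize_cohort, n_boot=0)


class TestLinearityTest:
    def test_no_spline_fails(self, midsize_cohort):
        fit = fit_modified_model(midsize_cohort, "basic_reduced", "pd_amci",
                                 penalty=FAST_PENALTY, interaction_basis="linear")
        with pytest.raises(ValueError, match="nothing to test"):
            linearity_test(fit)

    def test_zero_spline_coefficient_gives_p_one(self, midsize_fit):
        import copy

        fit = copy.copy(midsize_fit)
        fit.gamma = midsize_fit.gamma.copy()
        fit.gamma["spline"] = 0.0
        chi2, p, df = linearity_test(fit)
        assert chi2 == 0.0 and p == 1.0 and df == 1

    def test_type_one_error_under_linear_truth(self):
        # effect exactly linear in the risk score; rejection near nominal .05
        truth = linear_in_risk_truth(intercept=0.0, slope=-0.25)
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            co = simulate_cohort(CohortConfig(n_subjects=1500, seed=400 + rep), truth)
            fit = fit_modified_model(co, "basic_reduced", "pd_amci",
                                     penalty=FAST_PENALTY)
            _, p, _ = linearity_test(fit)
            rejections += p < 0.05
        assert 0.0 <= rejections / n_rep <= 0.15

    def test_power_against_plateau_effect(self):
        # effect plateaus at high risk score: strongly curved interaction
        truth = TruthParameters(
            effect_kind="custom",
            effect_params={"fn": lambda eta: -0.1 + -0.6 * np.tanh(np.clip(eta, None, 0.0) + 0.8)},
        )
        hits = 0
        for rep in range(6):
            co = simulate_cohort(CohortConfig(n_subjects=8000, seed=500 + rep), truth)
            fit = fit_modified_model(co, "full", "pd_amci", penalty=FAST_PENALTY)
            _, p, _ = linearity_test(fit)
            hits += p < 0.05
        assert hits >= 4


class TestHybridModel:
    def test_no_subgroup_effects_small_c_difference(self, midsize_cohort, midsize_fit):
        hybrid, comp = hybrid_effect_model(
            midsize_cohort, "full", "pd_amci", penalty=FAST_PENALTY,
            base_fit=midsize_fit,
        )
        assert abs(comp["c_difference"]) < 0.01
        assert comp["n"] == midsize_cohort.n
        assert set(f"subgroup:{k}" for k in DEFAULT_SUBGROUPS) <= set(hybrid.gamma.index)

    def test_large_sex_specific_effect_detected(self):
        truth = TruthParameters(
            effect_params={"log_hr": np.log(0.95), "subgroup_effects": {"female": -0.6}}
        )
        co = simulate_cohort(CohortConfig(n_subjects=8000, seed=601), truth)
        hybrid, comp = hybrid_effect_model(co, "full", "pd_amci", penalty=FAST_PENALTY)
        idx = list(hybrid.gamma.index).index("subgroup:female")
        se = np.sqrt(np.diag(hybrid.gamma_cov))[idx]
        g = hybrid.gamma["subgroup:female"]
        assert g < 0 and abs(g) > 2 * se
        assert g == pytest.approx(-0.6, abs=3 * se + 0.1)

    def test_single_level_subgroup_dropped(self, midsize_cohort):
        subgroups = {"always_true": lambda df: pd.Series(1.0, index=df.index)}
        with pytest.warns(UserWarning, match="single level"):
            hybrid, comp = hybrid_effect_model(
                midsize_cohort, "basic_reduced", "pd_amci", penalty=FAST_PENALTY,
                subgroups=subgroups,
            )
        assert "subgroup:always_true" not in hybrid.gamma.index
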