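"""Cohort analysis: exclusions, rates, ORs, mixed models, power."""

import numpy as np
import pandas as pd
import pytest

from ccmea.cohort_stats import (
    Rate,
    apply_exclusions,
    baseline_comparison,
    bonferroni_alpha,
    compare_groups,
    detection_rate,
    exclusion_accounting,
    fit_glmm_logit,
    fit_glmm_poisson,
    odds_ratio_2x2,
    power_two_proportions,
    rate_difference,
    report_from_counts,
    required_n_two_proportions,
    round_half_up,
    sample_size_with_dropout,
)
from ccmea.datasets import load_exclusion_accounting, load_prospective_outcomes
from ccmea.synthetic import CohortGenSpec, generate_cohort, generate_two_group_cohort


def test_round_half_up_matches_clinical_table_convention():
    assert round_half_up(1.25, 1) == 1.3  # banker's rounding would give 1.2
    assert round_half_up(3.75, 1) == 3.8
    assert round_half_up(0.004545, 4) == 0.0045


class TestExclusions:
    @staticmethod
    def screened_frame():
        screened, reasons = load_exclusion_accounting()
        rows = []
        i = 0
        for reason, k in reasons.items():
            for _ in range(k):
                rows.append({"patient_id": i, "excluded": True, "exclusion_reason": reason})
                i += 1
        while i < screened:
            rows.append({"patient_id": i, "excluded": False, "exclusion_reason": None})
            i += 1
        return pd.DataFrame(rows)

    def test_study_flow_reproduced(self):
        analysis, accounting = apply_exclusions(self.screened_frame())
        assert len(analysis) == 510
        assert accounting.n.sum() == 41

    def test_accounting_table_per_reason(self):
        _, reasons = load_exclusion_accounting()
        acc = exclusion_accounting(551, reasons)
        assert int(acc.loc[acc.item == "analyzed", "n"].iloc[0]) == 510
        assert int(acc.loc[acc.item == "total_excluded", "n"].iloc[0]) == 41

    def test_zero_exclusions_identity(self):
        df = pd.DataFrame({"excluded": [False] * 5, "exclusion_reason": [None] * 5})
        analysis, accounting = apply_exclusions(df)
        assert len(analysis) == 5 and len(accounting) == 0

    def test_all_excluded_full_accounting(self):
        df = pd.DataFrame({"excluded": [True] * 3, "exclusion_reason": ["ibd", "ibd", "prep"]})
        analysis, accounting = apply_exclusions(df)
        assert len(analysis) == 0
        assert accounting.n.sum() == 3

    def test_contradictory_flags_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(
                pd.DataFrame({"excluded": [False], "exclusion_reason": ["ibd"]})
            )
        with pytest.raises(ValueError):
            apply_exclusions(pd.DataFrame({"excluded": [True], "exclusion_reason": [None]}))


class TestRates:
    def test_printed_percentages(self):
        assert Rate(145, 270).display == 53.7
        assert Rate(34, 240).display == 14.2
        assert Rate(0, 50).display == 0.0

    def test_detection_rate_from_column_and_callable(self):
        df = pd.DataFrame({"adenoma": [1, 0, 1, 1], "n": [2, 0, 1, 3]})
        assert detection_rate(df, "adenoma").count == 3
        assert detection_rate(df, lambda r: r["n"] >= 2).count == 2

    def test_empty_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            detection_rate(pd.DataFrame({"adenoma": []}), "adenoma")

    def test_difference_point_estimates(self):
        assert rate_difference(Rate(145, 270), Rate(34, 240)).display == 39.5
        assert rate_difference(Rate(242, 270), Rate(96, 240)).display == 49.6
        assert rate_difference(Rate(10, 100), Rate(10, 100)).display == 0.0

    def test_newcombe_interval_brackets_point(self):
        d = rate_difference(Rate(145, 270), Rate(34, 240))
        assert d.ci_low_pp < d.point_pp < d.ci_high_pp
        # hybrid-score CI is asymmetric around the point estimate
        assert (d.point_pp - d.ci_low_pp) != pytest.approx(d.ci_high_pp - d.point_pp)

    def test_wald_option(self):
        d = rate_difference(Rate(50, 100), Rate(25, 100), method="wald")
        assert d.ci_low_pp < 25.0 < d.ci_high_pp


class TestOddsRatio:
    def test_balanced_table_is_unity(self):
        assert odds_ratio_2x2(10, 10, 10, 10)["or"] == 1.0

    def test_adr_table(self):
        r = odds_ratio_2x2(145, 125, 34, 206)
        assert round_half_up(r["or"], 2) == 7.03
        assert r["ci_low"] < r["or"] < r["ci_high"]
        assert not r["continuity_corrected"]

    def test_sparse_table_finite_without_zero_cells(self):
        r = odds_ratio_2x2(14, 256, 1, 239)
        assert not r["continuity_corrected"]  # min cell is 1, not 0
        assert np.isfinite(r["or"]) and np.isfinite(r["ci_high"])
        assert r["or"] == pytest.approx(14 * 239 / (256 * 1))

    def test_continuity_correction_on_zero_cell(self):
        r = odds_ratio_2x2(14, 256, 0, 240)
        assert r["continuity_corrected"]
        assert np.isfinite(r["or"]) and np.isfinite(r["ci_high"])
        assert r["or"] == pytest.approx(14.5 * 240.5 / (256.5 * 0.5))

    def test_double_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 10, 0, 10)


def test_bonferroni_levels():
    assert round_half_up(bonferroni_alpha(0.05, 11), 4) == 0.0045
    assert bonferroni_alpha(0.05, 1) == 0.05
    assert bonferroni_alpha(0.10, 4) == 0.025
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


class TestMixedModels:
    def test_null_group_effect_recovered(self):
        df = generate_two_group_cohort(log_or=0.0, log_irr=0.0, seed=5)
        el = fit_glmm_logit(df, "adenoma", group="group")
        assert el.ci_low <= 1.0 <= el.ci_high
        ep = fit_glmm_poisson(df, "n_polyps", group="group")
        assert ep.ci_low <= 1.0 <= ep.ci_high

    def test_degenerate_center_variance_shrinks(self):
        df = generate_two_group_cohort(center_sd=0.0, n_centers=4, seed=0)
        est = fit_glmm_logit(df, "adenoma", group="group")
        assert est.group_summary["random_intercept_sd"]["center"] < 0.15

    def test_all_zero_group_flagged_separation(self):
        df = generate_two_group_cohort(seed=1)
        df["y0"] = np.where(df.group == 1, df.adenoma, 0)
        est = fit_glmm_logit(df, "y0", group="group")
        assert "separation" in est.flags
        assert np.isnan(est.ratio)

    def test_single_center_rejected(self):
        df = generate_two_group_cohort(seed=2)
        df["center"] = "C1"
        with pytest.raises(ValueError):
            fit_glmm_logit(df, "adenoma", group="group")

    def test_estimate_ci_brackets_ratio(self):
        df = generate_two_group_cohort(seed=3)
        est = fit_glmm_poisson(df, "n_polyps", group="group")
        assert est.ci_low <= est.ratio <= est.ci_high
        assert est.ratio_type == "aIRR"
        assert 0.0 <= est.p_value <= 1.0


class TestCompareGroups:
    @pytest.fixture(scope="class")
    @staticmethod
    def report():
        cohort = generate_cohort(CohortGenSpec(n_patients=510, seed=3))
        return compare_groups(cohort, 2000.0)

    def test_eleven_outcomes(self, report):
        assert len(report) == 11
        assert report.type.value_counts().to_dict() == {"rate": 9, "mean": 2}

    def test_bonferroni_flags_consistent(self, report):
        level = bonferroni_alpha(0.05, 11)
        for _, row in report.dropna(subset=["p_value"]).iterrows():
            assert row.significant == (row.p_value < level)

    def test_effect_directions_favor_qualified(self, report):
        assert (report.qualified_value >= report.unqualified_value).all()

    def test_identical_groups_null_report(self):
        base = generate_cohort(CohortGenSpec(n_patients=200, seed=8)).drop(columns=["ccmea"])
        twin = pd.concat(
            [base.assign(ccmea=1000.0), base.assign(ccmea=3000.0)], ignore_index=True
        )
        report = compare_groups(twin, 2000.0)
        assert (report.abs_difference == 0).all()
        finite = report.ratio.dropna()
        assert np.allclose(finite, 1.0, atol=0.02)

    def test_single_group_rejected(self):
        cohort = generate_cohort(CohortGenSpec(n_patients=100, seed=1))
        with pytest.raises(ValueError):
            compare_groups(cohort, 10**9)


def test_report_from_counts_reproduces_printed_columns():
    report = report_from_counts(load_prospective_outcomes()).set_index("outcome")
    assert report.loc["adr", "qualified_pct"] == 53.7
    assert report.loc["adr", "unqualified_pct"] == 14.2
    assert report.loc["adr", "abs_difference_pp"] == 39.5
    assert report.loc["pdr", "abs_difference_pp"] == 49.6
    assert round_half_up(report.loc["adr", "unadjusted_or"], 2) == 7.03
    assert report.loc["mean_polyps", "abs_difference_pp"] == 4.5


class TestPower:
    def test_boundary_equals_alpha(self):
        assert power_two_proportions(0.3, 0.3, 0.05, 100) == pytest.approx(0.05, abs=1e-9)

    def test_design_point_in_expected_band(self):
        assert 0.68 <= power_two_proportions(0.33, 0.23, 0.05, 247) <= 0.76

    def test_monotone_in_n(self):
        p1 = power_two_proportions(0.33, 0.23, 0.05, 200)
        assert power_two_proportions(0.33, 0.23, 0.05, 400) >= p1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_two_proportions(1.2, 0.2, 0.05, 100)
        with pytest.raises(ValueError):
            power_two_proportions(0.3, 0.2, 0.0, 100)

    def test_inverse_mode_consistency(self):
        n = required_n_two_proportions(0.33, 0.23, 0.05, 0.74)
        assert power_two_proportions(0.33, 0.23, 0.05, n) >= 0.74
        assert power_two_proportions(0.33, 0.23, 0.05, n - 1) < 0.74

    def test_dropout_inflation(self):
        n = required_n_two_proportions(0.33, 0.23, 0.05, 0.74)
        assert sample_size_with_dropout(0.33, 0.23, 0.05, 0.74, 0.10) == int(
            np.ceil(2 * n / 0.9)
        )


def test_baseline_comparison_selection_rules():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "group": rng.integers(0, 2, 400),
            "age": rng.normal(58, 11, 400),
            "skewed": rng.exponential(2.0, 400) ** 2,
            "sex": rng.choice(["male", "female"], 400),
        }
    )
    out = baseline_comparison(
        df, "group", numeric=["age", "skewed"], categorical=["sex"]
    ).set_index("variable")
    assert out.loc["age", "test"] == "welch_t"
    assert out.loc["skewed", "test"] == "mann_whitney_u"
    assert out.loc["sex", "test"] in ("chi_squared", "fisher_exact")
    assert ((out.p_value >= 0) & (out.p_value <= 1)).all()
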