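"""Odds ratios, logistic fit, t-test, proportion ratio, sensitivity grid."""

import numpy as np
import pytest

from cusumlearn import (
    ContingencyTable2x2,
    FailureRateSpec,
    SeparationError,
    compare_cohorts,
    logistic_fit,
    odds_ratio,
    proportion_ratio,
    sensitivity_grid,
    welch_t_test,
)

from conftest import engineered_cohort, make_frame

# (study_yes, study_no, control_yes, control_no) -> published crude OR
PUBLISHED_TABLES = [
    ((14, 7, 8, 13), 3.25),
    ((16, 5, 16, 5), 1.0),
    ((9, 12, 7, 14), 1.5),
    ((16, 5, 14, 7), 1.6),
]


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expected", PUBLISHED_TABLES)
    def test_reproduces_published_point_estimates(self, cells, expected):
        res = odds_ratio(ContingencyTable2x2(*cells))
        assert res["or"] == pytest.approx(expected, abs=1e-12)
        assert not res["corrected"]
        assert res["ci_low"] <= res["or"] <= res["ci_high"]

    def test_woolf_interval_hand_check(self):
        # 14*13/(7*8), se = sqrt(1/14+1/7+1/8+1/13)
        res = odds_ratio(ContingencyTable2x2(14, 7, 8, 13))
        se = np.sqrt(1 / 14 + 1 / 7 + 1 / 8 + 1 / 13)
        z = 1.959963984540054
        assert res["ci_low"] == pytest.approx(3.25 * np.exp(-z * se), rel=1e-9)
        assert res["ci_high"] == pytest.approx(3.25 * np.exp(z * se), rel=1e-9)

    def test_zero_cell_triggers_continuity_correction(self):
        res = odds_ratio(ContingencyTable2x2(10, 0, 5, 5))
        assert res["corrected"]
        assert res["or"] == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_empty_margin_undefined(self):
        res = odds_ratio(ContingencyTable2x2(0, 0, 5, 5))
        assert res["or"] is None and res["pvalue"] is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 5, 5, 5)

    @pytest.mark.parametrize(
        "cells,pct",
        [
            ((14, 7, 8, 13), (67, 38)),
            ((16, 5, 16, 5), (76, 76)),
            ((9, 12, 7, 14), (43, 33)),
            ((13, 8, 7, 14), (62, 33)),
        ],
    )
    def test_percentages_round_half_away(self, cells, pct):
        assert ContingencyTable2x2(*cells).percentages() == pct


def outcomes_from_table(yes_s, no_s, yes_c, no_c):
    outcomes = [1] * yes_s + [0] * no_s + [1] * yes_c + [0] * no_c
    groups = ["study"] * (yes_s + no_s) + ["control"] * (yes_c + no_c)
    return outcomes, groups


class TestLogisticFit:
    @pytest.mark.parametrize("cells,expected", PUBLISHED_TABLES)
    def test_exp_slope_equals_crude_or(self, cells, expected):
        outcomes, groups = outcomes_from_table(*cells)
        res = logistic_fit(outcomes, groups, study_label="study")
        assert res["or"] == pytest.approx(expected, abs=1e-6)

    def test_identical_groups_give_unit_or(self):
        outcomes, groups = outcomes_from_table(5, 5, 5, 5)
        res = logistic_fit(outcomes, groups, study_label="study")
        assert res["or"] == pytest.approx(1.0, abs=1e-9)

    def test_separation_raises_diagnostic(self):
        outcomes, groups = outcomes_from_table(10, 0, 5, 5)
        with pytest.raises(SeparationError, match="separation"):
            logistic_fit(outcomes, groups, study_label="study")

    def test_agrees_with_statsmodels_glm(self):
        """Independent cross-check of the IRLS fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 80)
        y = (rng.random(80) < 0.3 + 0.3 * x).astype(int)
        if y[x == 0].min() == y[x == 0].max() or y[x == 1].min() == y[x == 1].max():
            pytest.skip("degenerate draw")  # pragma: no cover
        groups = np.where(x == 1, "study", "control")
        res = logistic_fit(y, groups, study_label="study")
        X = sm.add_constant(x.astype(float))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert res["coef"] == pytest.approx(ref.params[1], abs=1e-8)
        assert res["se"] == pytest.approx(ref.bse[1], abs=1e-6)

    def test_wald_p_matches_woolf_z(self):
        outcomes, groups = outcomes_from_table(14, 7, 8, 13)
        fit = logistic_fit(outcomes, groups, study_label="study")
        table = odds_ratio(ContingencyTable2x2(14, 7, 8, 13))
        assert fit["pvalue"] == pytest.approx(table["pvalue"], abs=1e-6)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res["t"] == 0 and res["pvalue"] == pytest.approx(1.0)

    def test_hand_evaluated_statistic(self):
        res = welch_t_test([1, 2, 3], [4, 5, 6])
        assert res["t"] == pytest.approx(-3.6742, abs=1e-4)
        assert res["df"] == pytest.approx(4.0, abs=1e-9)

    def test_zero_variance_equal_means_degenerate(self):
        res = welch_t_test([2, 2, 2], [2, 2])
        assert res["degenerate"] and res["pvalue"] == 1.0 and res["t"] == 0.0

    def test_zero_variance_unequal_means_degenerate(self):
        res = welch_t_test([2, 2], [3, 3])
        assert res["degenerate"] and res["pvalue"] == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1], [2, 3])


class TestProportionRatio:
    def test_equal_proportions(self):
        assert proportion_ratio(10, 20, 10, 20)["ratio"] == pytest.approx(1.0)

    def test_trainee_level_ratio(self):
        res = proportion_ratio(14, 21, 8, 21)
        assert res["ratio"] == pytest.approx(1.75)
        assert res["ci_low"] < 1.75 < res["ci_high"]

    def test_zero_numerator(self):
        res = proportion_ratio(0, 20, 10, 20)
        assert res["ratio"] == 0.0 and res["ci_low"] is None

    def test_zero_reference_undefined(self):
        assert proportion_ratio(5, 20, 0, 20)["ratio"] is None

    def test_bad_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_ratio(1, 0, 1, 5)


TABLE1_SETTINGS = [(0.10, 0.30), (0.10, 0.40), (0.20, 0.30), (0.20, 0.35), (0.20, 0.40)]


class TestSensitivityGrid:
    def test_single_setting_equals_direct_path(self, cohort_frame):
        spec = FailureRateSpec(0.10, 0.30, 0.10, 0.10)
        direct = compare_cohorts(cohort_frame, spec)
        grid = sensitivity_grid(cohort_frame, [(0.10, 0.30)], 0.10, 0.10)
        assert len(grid) == 1
        assert grid[0].comparison.to_dict() == direct.to_dict()

    def test_all_success_cohort_unit_or_with_correction(self):
        df = make_frame(
            {f"s{i}": [0] * 20 for i in range(3)}
            | {f"c{i}": [0] * 20 for i in range(3, 6)},
            groups={f"s{i}": "study" for i in range(3)}
            | {f"c{i}": "control" for i in range(3, 6)},
        )
        row = sensitivity_grid(df, [(0.10, 0.30)], 0.10, 0.10)[0]
        t = row.comparison.table
        assert (t.study_yes, t.control_yes) == (3, 3)
        assert row.comparison.continuity_corrected
        assert row.comparison.odds_ratio == pytest.approx(1.0)

    def test_raising_p1_moves_lower_crossing_earlier(self, cohort_frame):
        """With p0 fixed, widening p1 raises the lower line pointwise,
        so the first lower-line crossing never comes later and no
        competent trainee becomes indeterminate.  (Full status need
        not be monotone: the upper line also drops, so the
        unacceptable verdict can win the race instead.)"""
        import numpy as np

        from cusumlearn import compute_constants
        from cusumlearn.learning_curve import BOUNDARY_ATOL, series_from_frame
        from cusumlearn import boundary_values

        series = series_from_frame(cohort_frame)
        for p0 in (0.10, 0.20):
            first_lo = {}
            for p1 in (0.30, 0.35, 0.40):
                c = compute_constants(FailureRateSpec(p0, p1, 0.10, 0.10))
                crossings = {}
                for s in series:
                    n = np.arange(1, s.n_attempts + 1)
                    h0, _ = boundary_values(c, n)
                    below = s.cumsum <= h0 + BOUNDARY_ATOL
                    crossings[s.trainee_id] = (
                        int(below.argmax()) + 1 if below.any() else np.inf
                    )
                first_lo[p1] = crossings
            for lo, hi in [(0.30, 0.35), (0.35, 0.40)]:
                for tid in first_lo[lo]:
                    assert first_lo[hi][tid] <= first_lo[lo][tid]

    def test_engineered_counts_reproduce_published_or(self):
        df = engineered_cohort(14, 21, 8, 21)
        row = sensitivity_grid(df, [(0.10, 0.30)], 0.10, 0.10)[0]
        t = row.comparison.table
        assert (t.study_yes, t.control_yes) == (14, 8)
        assert row.comparison.odds_ratio == pytest.approx(3.25, abs=1e-12)

    def test_table1_grid_ordering_and_shape(self, cohort_frame):
        rows = sensitivity_grid(cohort_frame, TABLE1_SETTINGS, 0.10, 0.10)
        assert [(r.p0, r.p1) for r in rows] == TABLE1_SETTINGS

    def test_empty_settings_rejected(self, cohort_frame):
        with pytest.raises(ValueError):
            sensitivity_grid(cohort_frame, [], 0.10, 0.10)
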