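"""2x2 metrics, exact CIs, threshold sweeps and group-comparison tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from nvugib.diagnostics import (
    TwoByTwo,
    compare_means,
    compare_proportions,
    diagnostic_metrics,
    proportion_ci,
    select_optimal_threshold,
    threshold_sweep,
    two_by_two,
)

# Printed cumulative-table cells: sensitivity and specificity at every cutoff
# 0..17, for the GBS and for the combined-score rule.
GBS_SENS = [100, 97.1, 94.3, 91.4, 91.4, 91.4, 91.4, 88.6, 88.6, 82.9, 71.4,
            51.4, 34.3, 25.7, 22.9, 8.6, 2.9, 0]
GBS_SPEC = [3.8, 5.0, 7.5, 15.0, 16.2, 16.2, 23.8, 32.5, 35.0, 41.2, 52.5,
            65.0, 77.5, 86.2, 90.0, 93.8, 98.8, 100]
ALGO_SENS = [100] * 10 + [97.1, 94.3, 91.4, 82.9, 80.0, 71.4, 68.6, 68.6]
ALGO_SPEC = [3.8, 5.0, 7.5, 13.8, 15.0, 15.0, 20.0, 26.2, 28.8, 33.8, 45.0,
             55.0, 66.2, 73.8, 77.5, 80.0, 85.0, 86.2]


class TestTwoByTwo:
    def test_bloody_aspirate_rule(self, cohort):
        t = two_by_two(cohort, lambda r: r.bloody)
        assert (t.tp, t.fp, t.fn, t.tn) == (24, 11, 11, 69)

    def test_all_negative_rule(self, cohort):
        t = two_by_two(cohort, lambda r: False)
        assert t.tp == 0 and t.fp == 0
        assert t.fn == 35 and t.tn == 80

    def test_combined_score_above_nine(self, cohort, scores):
        _, comb, _ = scores
        by_id = dict(zip([r.id for r in cohort], comb))
        t = two_by_two(cohort, lambda r: by_id[r.id] > 9)
        assert (t.tp, t.fp, t.fn, t.tn) == (35, 53, 0, 27)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 0, 0, 0)


class TestDiagnosticMetrics:
    def test_bloody_aspirate_metrics(self):
        m = diagnostic_metrics(TwoByTwo(24, 11, 11, 69))
        assert round(m["sensitivity"].estimate, 1) == 68.6
        assert round(m["specificity"].estimate, 1) == 86.2
        assert round(m["ppv"].estimate, 1) == 68.6
        assert round(m["npv"].estimate, 1) == 86.2

    def test_perfect_table(self):
        m = diagnostic_metrics(TwoByTwo(1, 0, 0, 1))
        assert all(v.estimate == 100.0 for v in m.values())

    def test_clopper_pearson_3_of_80(self):
        ci = proportion_ci(3, 80)
        assert round(ci.ci_low, 1) == 0.8
        assert round(ci.ci_high, 1) == 10.6

    def test_clopper_pearson_hrel_rate_among_not_ruled_out(self):
        # HREL prevalence among the 112 patients the GBS<=0 rule keeps for
        # endoscopy (35/112) and among the 88 the combined rule keeps (35/88)
        ci = proportion_ci(35, 112)
        assert (round(ci.estimate, 1), round(ci.ci_low, 1),
                round(ci.ci_high, 1)) == (31.2, 22.8, 40.7)
        ci = proportion_ci(35, 88)
        assert (round(ci.estimate, 1), round(ci.ci_low, 1),
                round(ci.ci_high, 1)) == (39.8, 29.5, 50.8)

    def test_exact_coverage_endpoints(self):
        assert proportion_ci(0, 20).ci_low == 0.0
        assert proportion_ci(20, 20).ci_high == 100.0

    def test_ci_equivariant_under_success_failure_swap(self):
        a = proportion_ci(7, 31)
        b = proportion_ci(24, 31)
        assert a.ci_low == pytest.approx(100.0 - b.ci_high, abs=1e-9)
        assert a.ci_high == pytest.approx(100.0 - b.ci_low, abs=1e-9)

    def test_undefined_metric_reported_absent(self):
        m = diagnostic_metrics(TwoByTwo(0, 0, 3, 5))  # no positive tests
        assert m["ppv"] is None
        assert m["npv"] is not None

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(TwoByTwo(0, 0, 0, 0))


class TestThresholdSweep:
    def test_reproduces_all_printed_cells(self, cohort, scores):
        gbs, comb, _ = scores
        for per_score, sens, spec in (
            (gbs, GBS_SENS, GBS_SPEC),
            (comb, ALGO_SENS, ALGO_SPEC),
        ):
            rows = threshold_sweep(cohort, per_score)
            assert [r.sensitivity for r in rows] == pytest.approx(sens)
            assert [r.specificity for r in rows] == pytest.approx(spec)

    def test_first_row_counts_and_percentages(self, cohort, scores):
        gbs, _, _ = scores
        r0 = threshold_sweep(cohort, gbs)[0]
        assert (r0.cum_with, r0.cum_without) == (0, 3)
        assert (r0.sensitivity, r0.specificity) == (100.0, 3.8)
        assert r0.cum_without_pct == 2.6  # out of all 115 patients

    def test_sensitivity_identity(self, cohort, scores):
        gbs, _, _ = scores
        n_with = 35
        for r in threshold_sweep(cohort, gbs):
            assert r.sensitivity == pytest.approx(
                round(100.0 * (n_with - r.cum_with) / n_with, 1)
            )

    def test_out_of_range_scores_rejected(self, cohort):
        with pytest.raises(ValueError):
            threshold_sweep(cohort, [24] * len(cohort))


class TestOptimalThreshold:
    def test_study_thresholds(self, cohort, scores):
        gbs, comb, _ = scores
        assert select_optimal_threshold(threshold_sweep(cohort, gbs)) == 0
        assert select_optimal_threshold(threshold_sweep(cohort, comb)) == 9

    def test_all_sensitivities_pass_gives_max_cutoff(self, cohort, scores):
        _, comb, _ = scores
        rows = threshold_sweep(cohort, comb, cutoffs=range(10))
        assert select_optimal_threshold(rows) == 9

    def test_unreachable_floor(self, cohort, scores):
        gbs, _, _ = scores
        rows = threshold_sweep(cohort, gbs, cutoffs=range(5, 18))
        with pytest.raises(ValueError):
            select_optimal_threshold(rows)


def fisher_enumeration(x1, n1, x2, n2):
    """Oracle: sum hypergeometric probabilities of all tables with the same
    margins that are at most as probable as the observed one."""
    m = x1 + x2
    rv = hypergeom(n1 + n2, m, n1)
    p_obs = rv.pmf(x1)
    return sum(
        rv.pmf(k) for k in range(max(0, m - n2), min(m, n1) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestCompareProportions:
    def test_low_risk_proportion_comparison(self):
        assert compare_proportions(27, 115, 3, 115, "chi_square") < 0.001

    def test_identical_proportions_fisher(self):
        assert compare_proportions(5, 10, 5, 10, "fisher") == pytest.approx(1.0)

    def test_small_table_fisher(self):
        assert compare_proportions(2, 5, 3, 5, "fisher") == pytest.approx(1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(n1=st.integers(1, 10), n2=st.integers(1, 10), data=st.data())
    def test_fisher_equals_hypergeometric_enumeration(self, n1, n2, data):
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        p = compare_proportions(x1, n1, x2, n2, "fisher")
        assert p == pytest.approx(fisher_enumeration(x1, n1, x2, n2), abs=1e-9)

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 1, 2)


class TestCompareMeans:
    def test_gbs_by_stratum(self, scores):
        gbs, _, hrel = scores
        assert round(compare_means(gbs[hrel], gbs[~hrel]), 2) == 0.02

    def test_identical_groups(self):
        assert compare_means([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_means([0, 0, 0, 0], [1, 1, 1, 1])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_means([1.0], [1.0, 2.0])
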