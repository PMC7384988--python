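"""Concordance arithmetic, proportions, group comparisons, cost estimate."""
import itertools

import numpy as np
import pytest
from scipy import stats

from magee_triage import (
    CaseRecord,
    TriageLabel,
    build_concordance,
    cohort_proportions,
    compare_groups,
    cost_savings,
    subgroup_analysis,
    triage_cohort,
)
from magee_triage.cohort import DEFAULT_VARIABLE_SPEC

LOW = TriageLabel.DO_NOT_SEND_EXPECT_LOW
HIGH = TriageLabel.DO_NOT_SEND_EXPECT_HIGH
SEND = TriageLabel.SEND


def make_labels_rs(hh, hl, lh, ll, send_high=0, send_low=0):
    labels, rs = [], []
    for label, high, n in [
        (HIGH, True, hh), (HIGH, False, hl), (LOW, True, lh), (LOW, False, ll),
        (SEND, True, send_high), (SEND, False, send_low),
    ]:
        labels += [label] * n
        rs += [30.0 if high else 10.0] * n
    return labels, rs


class TestConcordance:
    def test_published_count_arithmetic(self):
        """The validation-table counts give 95.1 / 95.1 / 95.0 / 4.9 percent."""
        labels, rs = make_labels_rs(hh=19, hl=1, lh=75, ll=1443)
        s = build_concordance(labels, rs)
        assert s.n_do_not_send == 1538
        assert s.overall_accuracy_pct == 95.1
        assert s.expect_low_accuracy_pct == 95.1
        assert s.expect_high_accuracy_pct == 95.0
        assert s.discordant_fraction_pct == 4.9

    def test_all_concordant_is_perfect(self):
        labels, rs = make_labels_rs(hh=5, hl=0, lh=0, ll=20)
        s = build_concordance(labels, rs)
        assert s.overall_accuracy == 1.0
        assert s.expect_low_accuracy == 1.0 and s.expect_high_accuracy == 1.0

    def test_symmetric_table_is_half(self):
        labels, rs = make_labels_rs(hh=1, hl=1, lh=1, ll=1)
        assert build_concordance(labels, rs).overall_accuracy == 0.5

    def test_send_cases_excluded_but_tallied(self):
        labels, rs = make_labels_rs(hh=2, hl=0, lh=0, ll=8, send_high=3, send_low=7)
        s = build_concordance(labels, rs)
        assert s.n_do_not_send == 10 and s.n_send == 10
        assert s.send_high_fraction == 0.3

    def test_missing_rs_excluded_with_count(self):
        s = build_concordance([LOW, LOW, LOW], [10.0, None, float("nan")])
        assert s.n_missing_rs == 2 and s.n_do_not_send == 1

    def test_zero_do_not_send_not_applicable(self):
        s = build_concordance([SEND, SEND], [30.0, 10.0])
        assert s.overall_accuracy is None and s.expect_low_accuracy is None

    def test_cells_sum_to_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            hh, hl, lh, ll, sh, sl = rng.integers(0, 30, 6)
            labels, rs = make_labels_rs(hh, hl, lh, ll, sh, sl)
            s = build_concordance(labels, rs)
            assert s.n_expect_high == hh + hl
            assert s.n_expect_low == lh + ll
            assert s.n_do_not_send == hh + hl + lh + ll
            assert s.n_actual_high + s.n_actual_low == s.n_do_not_send

    def test_overall_is_weighted_mean_of_arm_accuracies(self):
        labels, rs = make_labels_rs(hh=19, hl=1, lh=75, ll=1443)
        s = build_concordance(labels, rs)
        weighted = (
            s.expect_high_accuracy * s.n_expect_high
            + s.expect_low_accuracy * s.n_expect_low
        ) / s.n_do_not_send
        assert s.overall_accuracy == pytest.approx(weighted, abs=1e-12)


class TestProportions:
    def test_published_split(self):
        # 1538/2196 = 70.036%; the printed percentages (70.1/29.9) carry the
        # source's own one-decimal rounding, so agreement is at that granularity
        labels = [LOW] * 1518 + [HIGH] * 20 + [SEND] * 658
        p = cohort_proportions(labels)
        assert p["do_not_send_fraction"] == pytest.approx(1538 / 2196)
        assert abs(p["do_not_send_pct"] - 70.1) <= 0.1 + 1e-9
        assert abs(p["send_pct"] - 29.9) <= 0.1 + 1e-9

    def test_zero_do_not_send(self):
        p = cohort_proportions([SEND] * 5)
        assert p["do_not_send_pct"] == 0.0

    def test_percents_sum_to_hundred_within_rounding(self):
        rng = np.random.default_rng(0)
        choices = [LOW, HIGH, SEND]
        for _ in range(20):
            labels = [choices[int(rng.integers(3))] for _ in range(int(rng.integers(1, 50)))]
            p = cohort_proportions(labels)
            assert abs(p["do_not_send_pct"] + p["send_pct"] - 100.0) <= 0.1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_proportions([])


def _case(i, **kw):
    base = dict(case_id=i, tumor_size=1.5, nottingham_score=6, mitosis_score=1,
                er_h_score=250, pr_h_score=150, her2_status="negative", ki67_index=10)
    base.update(kw)
    return CaseRecord(**base)


class TestSubgroup:
    def test_full_cohort_predicate_matches_plain_concordance(self, default_cohort):
        ct = triage_cohort(default_cohort)
        full = build_concordance(ct.results, [c.actual_rs for c in default_cohort])
        sub = subgroup_analysis(default_cohort, ct.results, lambda c: True)
        assert sub.concordance == full

    def test_banded_fractions_on_uniform_scores(self):
        cases = [_case(i, actual_rs=10.0, age=45) for i in range(5)]
        ct = triage_cohort(cases)
        sub = subgroup_analysis(cases, ct.results, lambda c: c.age <= 50)
        assert sub.frac_rs_lt_16 == 1.0 and sub.frac_rs_lt_21 == 1.0

    def test_empty_subgroup_not_applicable(self):
        cases = [_case(0, age=60)]
        ct = triage_cohort(cases)
        sub = subgroup_analysis(cases, ct.results, lambda c: c.age <= 50)
        assert not sub.applicable

    def test_age_subgroup_accuracy_tracks_full_cohort(self, default_cohort):
        ct = triage_cohort(default_cohort)
        full = build_concordance(ct.results, [c.actual_rs for c in default_cohort])
        young = subgroup_analysis(default_cohort, ct.results,
                                  lambda c: c.age is not None and c.age <= 50)
        assert young.applicable
        assert abs(young.concordance.overall_accuracy - full.overall_accuracy) <= 0.03


class TestCompareGroups:
    def _groups_from_2x2(self, a_neg, a_pos, b_neg, b_pos):
        ga = [_case(f"a{i}", pr_h_score=0) for i in range(a_neg)] + \
             [_case(f"a{i+a_neg}", pr_h_score=200) for i in range(a_pos)]
        gb = [_case(f"b{i}", pr_h_score=0) for i in range(b_neg)] + \
             [_case(f"b{i+b_neg}", pr_h_score=200) for i in range(b_pos)]
        return ga, gb

    def test_pr_status_published_table_significant(self):
        """Discordant 20/55 vs concordant 68/1375 PR-negative split: p < 0.0001."""
        ga, gb = self._groups_from_2x2(20, 55, 68, 1375)
        spec = {"pr_status": DEFAULT_VARIABLE_SPEC["pr_status"]}
        (res,) = compare_groups(ga, gb, spec)
        assert res.p_value < 0.0001

    def test_identical_balanced_groups_fisher_p_is_one(self):
        ga, gb = self._groups_from_2x2(3, 3, 3, 3)
        spec = {"pr_status": DEFAULT_VARIABLE_SPEC["pr_status"]}
        (res,) = compare_groups(ga, gb, spec)
        assert res.test == "fisher_exact"
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        ga = [_case(f"a{i}", age=float(rng.normal(60, 10)), pr_h_score=float(rng.integers(0, 301)))
              for i in range(40)]
        gb = [_case(f"b{i}", age=float(rng.normal(58, 12)), pr_h_score=float(rng.integers(0, 301)))
              for i in range(25)]
        fwd = compare_groups(ga, gb)
        rev = compare_groups(gb, ga)
        for f, r in zip(fwd, rev):
            if f.p_value is not None and not np.isnan(f.p_value):
                assert f.p_value == pytest.approx(r.p_value, rel=1e-9)

    def test_continuous_with_too_few_values_skipped(self):
        ga = [_case("a0", age=50.0)]
        gb = [_case(f"b{i}", age=60.0) for i in range(5)]
        spec = {"age": DEFAULT_VARIABLE_SPEC["age"]}
        (res,) = compare_groups(ga, gb, spec)
        assert res.test == "skipped" and res.p_value is None

    def test_welch_t_type_one_error_calibrated(self):
        """Null Welch t on equal normals rejects at ~5% over 2000 replicates."""
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, size=(2000, 500))
        b = rng.normal(0, 1, size=(2000, 500))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = float(np.mean(p < 0.05))
        assert abs(rate - 0.05) <= 0.02

    def test_chi_square_close_to_multinomial_oracle(self):
        """On small 2x2 tables the chi-square p is within 0.02 of an
        unconditional multinomial simulation under the pooled-margin null."""

        def simulated_p(table, reps=8000, seed=123):
            table = np.asarray(table, float)
            n = int(table.sum())
            probs = np.outer(table.sum(1), table.sum(0)).ravel() / n**2
            chi_obs = stats.chi2_contingency(table, correction=False)[0]
            rng = np.random.default_rng(seed)
            draws = rng.multinomial(n, probs, size=reps).reshape(reps, 2, 2)
            exceed = 0
            for t in draws:
                if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                    continue
                chi = stats.chi2_contingency(t, correction=False)[0]
                if chi >= chi_obs - 1e-9:
                    exceed += 1
            return exceed / reps

        for table in ([[12, 8], [7, 13]], [[14, 6], [8, 12]], [[15, 5], [8, 12]]):
            chi_p = stats.chi2_contingency(table, correction=False)[1]
            assert abs(chi_p - simulated_p(table)) <= 0.02


class TestCostSavings:
    def test_published_operating_point(self):
        s = cost_savings(100, 0.701, 4000)
        assert s.amount == pytest.approx(280400)

    def test_zero_requests(self):
        assert cost_savings(0, 0.7, 4000).amount == 0

    def test_all_avoided(self):
        assert cost_savings(100, 1.0, 4000).amount == 400000

    @pytest.mark.parametrize("frac", [-0.1, 1.1])
    def test_fraction_out_of_range_rejected(self, frac):
        with pytest.raises(ValueError):
            cost_savings(100, frac, 4000)
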