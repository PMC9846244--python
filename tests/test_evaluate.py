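"""Survival metrics against hand arithmetic, brute force, and the standard
survival packages as independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from milsurv.evaluate import (
    concordance_index,
    group_compare,
    hrd_classify,
    km_estimate,
    logrank_test,
    median_split,
    td_auc,
    ttest_from_summary,
)


def brute_force_cindex(times, censored, risks):
    """Exhaustive pair enumeration, written independently of the implementation."""
    n = len(times)
    conc = ties = comp = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shorter = times[i] < times[j] or (
                times[i] == times[j] and censored[i] == 0 and censored[j] == 1
            )
            if not (shorter and censored[i] == 0):
                continue
            comp += 1
            if risks[i] > risks[j]:
                conc += 1
            elif risks[i] == risks[j]:
                ties += 1
    return (conc + 0.5 * ties) / comp if comp else None


class TestConcordance:
    def test_perfect_ordering(self):
        r = concordance_index([5, 10, 15], [0, 0, 0], [0.9, 0.5, 0.1])
        assert r.c == 1.0 and r.comparable == 3

    def test_censored_pairs_by_hand(self):
        r = concordance_index([5, 10, 15], [0, 1, 0], [0.9, 0.5, 0.1])
        assert r.comparable == 2 and r.c == 1.0

    def test_all_risk_ties_give_half(self):
        assert concordance_index([1, 2, 3], [0, 0, 0], [7, 7, 7]).c == 0.5

    def test_orientation_flip_complements(self):
        t, c, r = [5, 10, 15, 20], [0, 0, 1, 0], [0.1, 0.9, 0.3, 0.7]
        a = concordance_index(t, c, r).c
        b = concordance_index(t, c, r, orientation="higher-risk-later-event").c
        assert a + b == pytest.approx(1.0)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index([5, 5], [1, 1], [1, 2])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 50))
            t = rng.integers(1, 20, n).astype(float)
            c = rng.integers(0, 2, n)
            r = np.round(rng.normal(size=n), 1)
            expected = brute_force_cindex(t, c, r)
            if expected is None:
                continue
            assert concordance_index(t, c, r).c == pytest.approx(expected)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_censored

        for _ in range(25):
            n = int(rng.integers(5, 40))
            t = rng.integers(1, 15, n).astype(float)
            c = rng.integers(0, 2, n)
            r = np.round(rng.normal(size=n), 1)
            if (c == 0).sum() == 0:
                continue
            try:
                mine = concordance_index(t, c, r).c
            except ValueError:
                continue
            ref = concordance_index_censored((c == 0), t, r)[0]
            assert mine == pytest.approx(ref, abs=1e-12)


class TestKaplanMeier:
    def test_all_events_by_hand(self):
        km = km_estimate([2, 4, 6], [0, 0, 0])
        assert km.at(2) == pytest.approx(2 / 3)
        assert km.at(4) == pytest.approx(1 / 3)
        assert km.at(6) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        km = km_estimate([2, 4, 6], [0, 1, 0])
        assert km.at(2) == pytest.approx(2 / 3)
        assert km.at(6) == pytest.approx(0.0)  # 1 at risk at t=6

    def test_all_censored_flat_curve(self):
        km = km_estimate([2, 4, 6], [1, 1, 1])
        assert km.event_times.size == 0
        assert km.at(100.0) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.integers(1, 30, 40).astype(float)
        km = km_estimate(t, np.zeros(40, int))
        for ti in np.unique(t):
            assert km.at(ti) == pytest.approx(np.mean(t > ti))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(12, 50).round(1) + 0.1
        c = rng.integers(0, 2, 50)
        km = km_estimate(t, c)
        kmf = KaplanMeierFitter().fit(t, event_observed=1 - c)
        for ti in np.unique(t):
            assert km.at(ti) == pytest.approx(float(kmf.predict(ti)), abs=1e-10)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t, c = [3, 6, 9, 12], [0, 0, 1, 0]
        res = logrank_test(t, c, t, c)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(10, 20), rng.exponential(20, 20)
        ca, cb = rng.integers(0, 2, 20), rng.integers(0, 2, 20)
        r1 = logrank_test(ta, ca, tb, cb)
        r2 = logrank_test(tb, cb, ta, ca)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_separated_groups_match_lifelines(self):
        from lifelines.statistics import logrank_test as ll

        res = logrank_test([1, 2, 3], [0, 0, 0], [4, 5, 6], [0, 0, 0])
        ref = ll([1, 2, 3], [4, 5, 6], event_observed_A=[1, 1, 1],
                 event_observed_B=[1, 1, 1])
        assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_random_instances_match_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll

        for _ in range(20):
            na, nb = rng.integers(5, 30, 2)
            ta = rng.integers(1, 20, na).astype(float)
            tb = rng.integers(1, 20, nb).astype(float)
            ca = rng.integers(0, 2, na)
            cb = rng.integers(0, 2, nb)
            if (ca == 1).all() and (cb == 1).all():
                continue
            res = logrank_test(ta, ca, tb, cb)
            ref = ll(ta, tb, event_observed_A=1 - ca, event_observed_B=1 - cb)
            assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-9)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [3, 4], [1, 1])


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([2.1, 2.5, 2.7, 1.9])
        assert list(labels) == ["low", "high", "high", "low"]

    def test_tie_at_median_goes_low(self):
        assert list(median_split([1, 2, 3])) == ["low", "low", "high"]

    def test_constant_scores_warn_all_low(self):
        with pytest.warns(UserWarning):
            labels = median_split([5.0, 5.0, 5.0])
        assert list(labels) == ["low"] * 3

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=30))
    def test_always_partitions(self, scores):
        labels = median_split(scores)
        assert set(labels) <= {"high", "low"}
        if len(set(scores)) > 1 and len(scores) % 2 == 0:
            med = np.median(scores)
            if not np.any(np.asarray(scores) == med):
                assert (labels == "high").sum() == len(scores) // 2


class TestTdAuc:
    def test_perfect_separation(self):
        t = np.array([2, 4, 20, 30.0])
        r = np.array([0.9, 0.8, 0.1, 0.2])
        assert td_auc(t, np.zeros(4, int), r, 10.0) == 1.0

    def test_equal_risks_give_half(self):
        t = np.array([2, 4, 20, 30.0])
        assert td_auc(t, np.zeros(4, int), np.ones(4), 10.0) == 0.5

    def test_reduces_to_mann_whitney_without_censoring(self, rng):
        t = rng.exponential(10, 60)
        r = rng.normal(size=60)
        hz = float(np.median(t))
        pos, ctrl = t <= hz, t > hz
        ref = mannwhitneyu(r[pos], r[ctrl]).statistic / (pos.sum() * ctrl.sum())
        assert td_auc(t, np.zeros(60, int), r, hz) == pytest.approx(ref, abs=1e-12)

    def test_matches_scikit_survival_with_censoring(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc

        for _ in range(10):
            t = rng.exponential(10, 50) + 0.1
            c = rng.integers(0, 2, 50)
            r = rng.normal(size=50)
            hz = float(np.quantile(t, 0.5))
            try:
                mine = td_auc(t, c, r, hz)
            except ValueError:
                continue
            y = np.array(list(zip(c == 0, t)), dtype=[("e", "?"), ("t", "<f8")])
            ref = cumulative_dynamic_auc(y, y, r, [hz])[0][0]
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_undefined_without_events_before_horizon(self):
        with pytest.raises(ValueError):
            td_auc([20, 30.0], [0, 0], [1, 2], 10.0)


class TestHRD:
    def test_sum_and_strict_threshold(self):
        assert hrd_classify(20, 15, 10).positive          # 45 > 42
        assert not hrd_classify(14, 14, 14).positive      # 42 is negative
        assert not hrd_classify(0, 0, 0).positive
        assert hrd_classify(20, 15, 10).hrd_score == 45

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            hrd_classify(-1, 5, 5)


class TestGroupCompare:
    def test_identical_groups_t(self):
        stat, p = group_compare([1, 2, 3], [1, 2, 3], "t")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_summary_t_reference_age_rows(self):
        # mean 58.13 sd 10.40 n 45 vs mean 61.78 sd 11.08 n 45
        stat, p = ttest_from_summary(58.13, 10.40, 45, 61.78, 11.08, 45)
        pooled = np.sqrt((44 * 10.40**2 + 44 * 11.08**2) / 88)
        expected = (58.13 - 61.78) / (pooled * np.sqrt(2 / 45))
        assert stat == pytest.approx(expected, rel=1e-10)
        assert abs(stat) == pytest.approx(1.61, abs=0.01)

    def test_spearman_self_correlation(self):
        rho, _ = group_compare([1, 3, 2, 5], [1, 3, 2, 5], "spearman")
        assert rho == pytest.approx(1.0)

    def test_wilcoxon_shift_detected(self, rng):
        a = rng.normal(0, 1, 40)
        stat, p = group_compare(a, a + 3, "wilcoxon")
        assert p < 1e-6

    def test_chisq_on_contingency_table(self):
        stat, p = group_compare([[10, 20], [30, 5]], None, "chisq")
        from scipy.stats import chi2_contingency

        ref = chi2_contingency([[10, 20], [30, 5]])
        assert stat == pytest.approx(ref.statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1, 2], "t")
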