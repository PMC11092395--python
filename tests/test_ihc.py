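"""H-score formula, DeLong AUC machinery, contingency and rank-sum tests,
logistic combination and correlation clustering."""

import numpy as np
import pandas as pd
import pytest

from panelforge import (
    auc_delong,
    compare_auc_delong,
    compute_hscore,
    correlation_cluster,
    logistic_combination,
    positivity_tests,
    rank_sum_test,
)
from panelforge.ihc import add_hscore

from oracles import auc_oracle, bootstrap_auc_variance, fisher_oracle, rank_sum_oracle


class TestHscore:
    @pytest.mark.parametrize(
        "w,m,s,expected", [(0, 0, 100, 300), (20, 30, 10, 110), (0, 0, 0, 0), (100, 0, 0, 100)]
    )
    def test_worked_examples(self, w, m, s, expected):
        assert compute_hscore(w, m, s) == expected

    def test_invalid_percentages_rejected(self):
        with pytest.raises(ValueError):
            compute_hscore(-1, 0, 0)
        with pytest.raises(ValueError):
            compute_hscore(60, 30, 20)

    def test_monotone_in_each_percentage(self):
        base = compute_hscore(10, 10, 10)
        assert compute_hscore(15, 10, 10) > base
        assert compute_hscore(10, 15, 10) > base
        assert compute_hscore(10, 10, 15) > base

    def test_add_hscore_column(self):
        table = pd.DataFrame(
            {"pct_weak": [10.0], "pct_moderate": [20.0], "pct_strong": [5.0]}
        )
        assert add_hscore(table).hscore.iloc[0] == 10 + 40 + 15


class TestAUCDeLong:
    def test_worked_example(self):
        r = auc_delong([1, 2, 3, 0, 1.5], ["p"] * 3 + ["n"] * 2, positive_label="p")
        assert r.raw_auc == pytest.approx(5 / 6)

    def test_perfect_separation_degenerate_ci(self):
        r = auc_delong([3, 4, 5, 0, 1], ["p"] * 3 + ["n"] * 2, positive_label="p")
        assert r.auc == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)

    def test_matches_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 7))
            scores = np.round(rng.normal(size=m + n), 1)  # rounding forces ties
            labels = ["p"] * m + ["n"] * n
            r = auc_delong(scores, labels, positive_label="p", orient=False)
            assert r.auc == auc_oracle(scores[:m], scores[m:])

    def test_orientation_reports_auc_at_least_half(self):
        r = auc_delong([0, 1, 5, 6], ["p", "p", "n", "n"], positive_label="p")
        assert r.auc == 1.0 and r.raw_auc == 0.0
        assert r.direction == "n"

    def test_variance_agrees_with_bootstrap(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(1.0, 1.0, size=30)
        neg = rng.normal(0.0, 1.0, size=30)
        r = auc_delong(
            np.concatenate([pos, neg]), ["p"] * 30 + ["n"] * 30, positive_label="p"
        )
        boot = bootstrap_auc_variance(pos, neg, n_boot=10000, rng=rng)
        assert r.se**2 == pytest.approx(boot, rel=0.15)

    def test_ci_ordered_and_bounded(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=20)
        r = auc_delong(scores, ["p"] * 10 + ["n"] * 10, positive_label="p")
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([1, 2], ["p", "p"])


class TestCompareDeLong:
    def test_marker_vs_itself(self):
        s = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.7])
        labels = ["p", "p", "p", "n", "n", "n"]
        c = compare_auc_delong(s, s, labels)
        assert c.auc_difference == 0.0 and c.p_value == 1.0

    def test_monotone_transform_identical_auc(self):
        s = np.array([0.5, 2.0, 1.0, 0.2, 0.4, 1.5])
        labels = ["p", "p", "p", "n", "n", "n"]
        c = compare_auc_delong(s, s**2, labels)  # positive scores: rank-preserving
        assert c.auc_difference == 0.0 and c.p_value == 1.0

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(3)
        s1, s2 = rng.normal(size=20), rng.normal(size=20)
        labels = ["p"] * 10 + ["n"] * 10
        c12 = compare_auc_delong(s1, s2, labels)
        c21 = compare_auc_delong(s2, s1, labels)
        assert c12.z_statistic == pytest.approx(-c21.z_statistic)
        assert c12.p_value == pytest.approx(c21.p_value)

    def test_mismatched_patients_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_delong([1, 2, 3], [1, 2], ["p", "p", "n"])


class TestPositivity:
    def test_ck7_discovery_table_matches_enumeration(self):
        # positive/negative x PAIM/lmCRC: 21/22 vs 2/17 positive
        table = [[21, 2], [1, 15]]
        res = positivity_tests(table)
        assert res["fisher_p"] == pytest.approx(fisher_oracle(table), abs=1e-10)
        assert res["positivity_pct"]["group_a"] == pytest.approx(100 * 21 / 22)
        assert res["positivity_pct"]["group_b"] == pytest.approx(100 * 2 / 17)

    def test_identical_proportions_p_one(self):
        assert positivity_tests([[5, 5], [5, 5]])["fisher_p"] == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        res = positivity_tests([[0, 0], [5, 7]])
        assert res["fisher_p"] == 1.0 and res["zero_margin"]

    def test_combined_cohort_ck7_positivity(self):
        # combined cohorts: 32/33 PAIM vs 7/36 lmCRC positive
        res = positivity_tests([[32, 7], [1, 29]])
        assert round(res["positivity_pct"]["group_a"], 1) == 97.0
        assert round(res["positivity_pct"]["group_b"], 1) == 19.4


class TestLogisticCombination:
    @staticmethod
    def noisy_scores(rng, n=20, shift=1.0):
        labels = np.array(["A"] * n + ["B"] * n)
        m1 = np.concatenate([rng.normal(shift, 1, n), rng.normal(0, 1, n)])
        m2 = np.concatenate([rng.normal(shift, 1, n), rng.normal(0, 1, n)])
        return pd.DataFrame({"m1": m1, "m2": m2}), labels

    def test_single_marker_recovers_raw_auc(self):
        rng = np.random.default_rng(4)
        hs, labels = self.noisy_scores(rng)
        coef, roc, separated = logistic_combination(hs[["m1"]], labels, positive_label="A")
        raw = auc_delong(hs["m1"], labels, positive_label="A")
        assert roc.auc == pytest.approx(max(raw.raw_auc, 1 - raw.raw_auc))
        assert not separated

    def test_two_independent_markers_do_not_hurt(self):
        rng = np.random.default_rng(5)
        worst_drop = 0.0
        for _ in range(20):
            hs, labels = self.noisy_scores(rng, shift=1.2)
            _, roc, _ = logistic_combination(hs, labels, positive_label="A")
            singles = [
                auc_delong(hs[c], labels, positive_label="A").auc for c in hs.columns
            ]
            worst_drop = max(worst_drop, max(singles) - roc.auc)
        assert worst_drop <= 0.02

    def test_complete_separation_detected_with_valid_auc(self):
        hs = pd.DataFrame({"m": [10.0, 11.0, 12.0, 0.0, 1.0, 2.0],
                           "m2": [1, 2, 1, 2, 1, 2.0]})
        labels = np.array(["A"] * 3 + ["B"] * 3)
        coef, roc, separated = logistic_combination(hs, labels, positive_label="A")
        assert separated
        assert not np.isfinite(coef.drop("const")).any()
        assert roc.auc == 1.0

    def test_constant_column_rejected(self):
        hs = pd.DataFrame({"m": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            logistic_combination(hs, ["A", "A", "B", "B"])


class TestCorrelationCluster:
    def test_duplicate_sample_same_cluster(self):
        rng = np.random.default_rng(6)
        samples = pd.DataFrame(rng.normal(size=(5, 8)))
        samples.loc[5] = samples.loc[0]
        res = correlation_cluster(samples)
        assert res.correlation.loc[5, 0] == pytest.approx(1.0)
        assert res.assignments[5] == res.assignments[0]
        assert np.allclose(np.diag(res.correlation), 1.0)

    def test_disjoint_profiles_match_labels_exactly(self):
        rng = np.random.default_rng(7)
        a = np.tile([5.0, 5, 0, 0, 0, 0], (6, 1)) + rng.normal(0, 0.2, (6, 6))
        b = np.tile([0.0, 0, 0, 0, 5, 5], (6, 1)) + rng.normal(0, 0.2, (6, 6))
        samples = pd.DataFrame(np.vstack([a, b]))
        res = correlation_cluster(samples, labels=["A"] * 6 + ["B"] * 6)
        assert res.agreement == 1.0

    def test_zero_variance_sample_rejected(self):
        samples = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            correlation_cluster(samples)


class TestRankSum:
    def test_worked_example(self):
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0.0 and p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            u, p = rank_sum_test(x, y)
            u_want, p_want = rank_sum_oracle(x, y)
            assert u == pytest.approx(u_want)
            assert p == pytest.approx(p_want, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
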