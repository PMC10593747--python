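"""Metric oracles: AUROC vs O(n^2) pair counting, AUPRC vs step-sum,
DeLong calibration under the null, printed-formula threshold metrics."""

import numpy as np
import pytest

from hdtft.metrics import (
    DegenerateLabelsError,
    auprc,
    auroc,
    calibration_curve,
    delong_test,
    metric_result,
    metrics_by_elapsed_time,
    precision_recall_f1,
)


def pair_counting_auroc(scores, labels):
    """O(n^2) concordance oracle; ties count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def step_sum_auprc(scores, labels):
    """Direct step integration over distinct thresholds."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    total_pos = y.sum()
    area = 0.0
    prev_recall = 0.0
    i = 0
    n = len(s)
    tp = fp = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestAuroc:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        assert auroc(s, y)[0] == 1.0

    def test_constant_scores_half(self):
        s = np.ones(10)
        y = np.array([1, 0] * 5)
        assert auroc(s, y)[0] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_pair_counting_oracle_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 200
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n) + y, 1)  # rounding forces ties
            a, _ = auroc(s, y)
            assert abs(a - pair_counting_auroc(s, y)) < 1e-12

    def test_ci_contains_point(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        s = rng.normal(size=100) + y
        a, (lo, hi) = auroc(s, y)
        assert lo <= a <= hi


class TestAuprc:
    def test_perfect_classifier(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        assert auprc(s, y, n_bootstrap=0)[0] == 1.0

    def test_constant_scores_equal_prevalence(self):
        y = np.array([1, 0, 0, 0, 1])
        a, _ = auprc(np.ones(5), y, n_bootstrap=0)
        assert a == pytest.approx(0.4)

    def test_step_sum_oracle_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = 150
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n) + 0.5 * y, 1)
            a, _ = auprc(s, y, n_bootstrap=0)
            assert abs(a - step_sum_auprc(s, y)) < 1e-12

    def test_bootstrap_ci_is_seeded(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 80)
        s = rng.normal(size=80) + y
        assert auprc(s, y, n_bootstrap=100, seed=5) == auprc(
            s, y, n_bootstrap=100, seed=5
        )

    def test_never_below_prevalence_for_constant_scores(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            a, _ = auprc(np.full(60, 0.3), y, n_bootstrap=0)
            assert a >= y.mean() - 1e-12


class TestDelong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        s = rng.normal(size=50)
        diff, p = delong_test(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_null_rejection_rate_calibrated(self):
        """Two noisy copies of the same signal: p-values ~ uniform; the
        rejection rate at alpha=0.05 lies in [0.03, 0.07] over 500
        replicates."""
        rng = np.random.default_rng(29)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            n = 150
            y = rng.integers(0, 2, n)
            while y.min() == y.max():
                y = rng.integers(0, 2, n)
            signal = rng.normal(size=n) + y
            a = signal + rng.normal(scale=0.8, size=n)
            b = signal + rng.normal(scale=0.8, size=n)
            _, p = delong_test(a, b, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_agrees_with_permutation_oracle_small_fixture(self):
        rng = np.random.default_rng(77)
        n = 30
        y = np.array([0, 1] * 15)
        sig = rng.normal(size=n) + 0.8 * y
        a = sig + rng.normal(scale=0.6, size=n)
        b = rng.normal(size=n) + 0.2 * y
        diff, p = delong_test(a, b, y)

        # permutation oracle: swap each pair's model assignment at random
        def auc(s):
            return auroc(s, y)[0]

        obs = abs(auc(a) - auc(b))
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            flip = rng.random(n) < 0.5
            aa = np.where(flip, b, a)
            bb = np.where(flip, a, b)
            count += abs(auc(aa) - auc(bb)) >= obs - 1e-12
        p_perm = count / n_perm
        assert abs(p - p_perm) < 0.05


class TestThresholdMetrics:
    def test_perfect(self):
        p, r, f1 = precision_recall_f1([0.9], [1])
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_printed_formula_values(self):
        # TP=3, FP=1, FN=2
        probs = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1]
        labels = [1, 1, 1, 0, 1, 1]
        p, r, f1 = precision_recall_f1(probs, labels)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)
        assert f1 == pytest.approx(2 * 0.45 / 1.35)

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            p, r, f1 = precision_recall_f1([0.1, 0.2], [0, 0])
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_formula_oracle_random_counts(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            n = 50
            probs = rng.random(n)
            labels = rng.integers(0, 2, n)
            p, r, f1 = precision_recall_f1(probs, labels)
            pred = probs >= 0.5
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            fn = int((~pred & (labels == 1)).sum())
            ep = tp / (tp + fp) if tp + fp else 0.0
            er = tp / (tp + fn) if tp + fn else 0.0
            ef = 2 * ep * er / (ep + er) if ep + er else 0.0
            assert (p, r, f1) == (ep, er, ef)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            precision_recall_f1([0.5], [1], threshold=1.0)


class TestCalibration:
    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        y = rng.integers(0, 2, 500)
        bins = calibration_curve(p, y)
        assert sum(c for _, _, c in bins) == 500

    def test_single_bin_all_half(self):
        p = np.full(100, 0.5)
        y = np.array([0, 1] * 50)
        bins = calibration_curve(p, y)
        assert len(bins) == 1
        assert bins[0][0] == 0.5 and bins[0][1] == 0.5

    def test_calibrated_probabilities_within_binomial_bounds(self):
        from scipy import stats as sps

        rng = np.random.default_rng(23)
        p = rng.random(20_000)
        y = (rng.random(20_000) < p).astype(int)
        for mean_p, obs, n in calibration_curve(p, y):
            lo = sps.binom.ppf(0.005, n, mean_p) / n
            hi = sps.binom.ppf(0.995, n, mean_p) / n
            assert lo <= obs <= hi

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5], [1], n_bins=1)


class TestElapsedStratification:
    def test_degenerate_bin_marked_undefined(self):
        s = np.array([0.2, 0.8, 0.5, 0.6])
        y = np.array([1, 1, 0, 1])  # first bin all-positive
        t = np.array([5.0, 10.0, 40.0, 50.0])
        rows = metrics_by_elapsed_time(s, y, t, bin_width_min=30)
        assert rows[0]["auroc"] is None
        assert rows[1]["auroc"] is not None

    def test_single_spanning_bin_equals_pooled(self):
        rng = np.random.default_rng(3)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        t = rng.uniform(0, 100, 200)
        rows = metrics_by_elapsed_time(s, y, t, bin_width_min=1000)
        assert rows[0]["auroc"] == auroc(s, y)[0]

    def test_subset_recomputation_exact(self):
        rng = np.random.default_rng(4)
        s = rng.random(500)
        y = rng.integers(0, 2, 500)
        t = rng.uniform(0, 240, 500)
        for row in metrics_by_elapsed_time(s, y, t, bin_width_min=30):
            sel = (t >= row["bin_start_min"]) & (t < row["bin_end_min"])
            assert row["count"] == int(sel.sum())
            if row["auroc"] is not None:
                assert row["auroc"] == auroc(s[sel], y[sel])[0]


def test_metric_result_consistency():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 300)
    s = np.clip(rng.normal(0.5, 0.2, 300) + 0.2 * y, 0, 1)
    m = metric_result(s, y, n_bootstrap=50)
    assert m.auroc_ci[0] <= m.auroc <= m.auroc_ci[1]
    if m.precision + m.recall > 0:
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall)
        )
    assert m.n_pos + m.n_neg == 300
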