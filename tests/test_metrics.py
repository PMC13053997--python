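"""Confusion arithmetic, AUROC/DeLong, Youden, BH: oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from fittriage.diff_abundance import mann_whitney_u
from fittriage.metrics import (
    bh_adjust,
    confusion_from_counts,
    confusion_metrics,
    delong_test,
    display_percent,
    evaluate_scores,
    roc_auc,
    youden_threshold,
)


def pairwise_auc_oracle(scores, labels):
    """Brute-force AUROC over all case-control pairs, ties half credit."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


class TestConfusion:
    def test_published_benchmark_counts(self):
        # 37/50 controls and 83/91 cases correct
        rep = confusion_from_counts(tp=83, fp=13, tn=37, fn=8)
        assert rep.specificity == pytest.approx(0.74)
        assert rep.sensitivity == pytest.approx(83 / 91)
        assert rep.balanced_accuracy == pytest.approx(0.5 * (0.74 + 83 / 91))
        disp = rep.display()
        assert disp["specificity_pct"] == 74
        assert disp["balanced_accuracy_pct"] == 83

    def test_adenoma_subgroup_sensitivity(self):
        rep = confusion_from_counts(tp=37, fp=0, tn=1, fn=8)
        assert rep.sensitivity == pytest.approx(37 / 45)
        assert display_percent(rep.sensitivity) == 82

    def test_perfect_scores(self):
        rep = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], threshold=0.5)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.balanced_accuracy == 1.0

    def test_single_class_flagged_undefined(self):
        rep = confusion_metrics([0.6, 0.7], [1, 1], threshold=0.5)
        assert rep.undefined
        assert np.isnan(rep.specificity)

    def test_balanced_accuracy_is_mean_of_recalls(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.random(30)
            y = (rng.random(30) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            rep = confusion_metrics(s, y, threshold=0.5)
            assert rep.balanced_accuracy == pytest.approx(
                0.5 * (rep.sensitivity + rep.specificity)
            )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_small_example_matches_pair_counting(self):
        scores = [0.9, 0.8, 0.85, 0.1]
        labels = [1, 1, 0, 0]
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc_oracle(scores, labels))
        assert auc == pytest.approx(0.75)

    def test_matches_pair_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = rng.integers(0, 5, size=20) / 4.0  # heavy ties
            y = (rng.random(20) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            auc, _, _ = roc_auc(s, y)
            assert auc == pytest.approx(pairwise_auc_oracle(s, y))

    def test_equals_mwu_u_over_pair_count(self):
        rng = np.random.default_rng(2)
        cases = rng.normal(1, 1, 15)
        controls = rng.normal(0, 1, 12)
        u, _ = mann_whitney_u(cases, controls)
        auc, _, _ = roc_auc(np.concatenate([cases, controls]), [1] * 15 + [0] * 12)
        assert auc == pytest.approx(u / (15 * 12))

    def test_complement_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.4).astype(int)
        a1, _, _ = roc_auc(s, y)
        a2, _, _ = roc_auc(-s, y)
        assert a1 + a2 == pytest.approx(1.0)
        a3, _, _ = roc_auc(np.exp(2 * s), y)
        assert a3 == pytest.approx(a1)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(4)
        s = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        y = np.array([1] * 30 + [0] * 30)
        auc, (lo, hi), _ = roc_auc(s, y)
        assert lo <= auc <= hi

    def test_all_tied_scores_degenerate(self):
        auc, ci, _ = roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == 0.5
        assert np.isnan(ci[0])


class TestYouden:
    def test_perfect_classifier(self):
        _, _, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        t, sens, spec = youden_threshold(roc)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_threshold_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        _, _, roc = roc_auc(scores, labels)
        t, sens, spec = youden_threshold(roc)
        best_j, best_t = -np.inf, None
        for cand in np.unique(scores):
            pred = scores >= cand
            se = (pred & (labels == 1)).sum() / 3
            sp = (~pred & (labels == 0)).sum() / 3
            j = se + sp - 1
            if j > best_j or (j == best_j and cand < best_t):
                best_j, best_t = j, cand
        assert t == pytest.approx(best_t)
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_random_scores_low_j(self):
        rng = np.random.default_rng(5)
        s = rng.random(400)
        y = (rng.random(400) < 0.5).astype(int)
        _, _, roc = roc_auc(s, y)
        _, sens, spec = youden_threshold(roc)
        assert sens + spec - 1 < 0.2


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(int)
        assert delong_test(s, s, y) == 1.0

    def test_informative_vs_noise_significant(self):
        rng = np.random.default_rng(7)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        good = y + rng.normal(0, 0.5, n)
        noise = rng.normal(size=n)
        assert delong_test(good, noise, y) < 0.01

    def test_close_to_paired_bootstrap_oracle(self):
        rng = np.random.default_rng(8)
        n = 60
        y = np.array([0, 1] * (n // 2))
        a = y + rng.normal(0, 1.2, n)
        b = y + rng.normal(0, 1.6, n)
        p_delong = delong_test(a, b, y)

        def auc(s, yy):
            r = stats.rankdata(s)
            m = (yy == 1).sum()
            return (r[yy == 1].sum() - m * (m + 1) / 2) / (m * (yy == 0).sum())

        obs = auc(a, y) - auc(b, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            boots.append(auc(a[idx], y[idx]) - auc(b[idx], y[idx]))
        boots = np.asarray(boots)
        se = boots.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(obs) / se)
        assert abs(p_delong - p_boot) < 0.05


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def test_subgroup_reports_present():
    rng = np.random.default_rng(10)
    groups = np.array(["G1"] * 20 + ["G2"] * 15 + ["G3"] * 15)
    y = (groups != "G1").astype(int)
    s = y * 0.5 + rng.random(50) * 0.5
    rep = evaluate_scores(s, y, sample_groups=groups)
    assert set(rep.subgroups) == {"G2_vs_G1", "G3_vs_G1"}
    for sub in rep.subgroups.values():
        assert 0 <= sub.auroc <= 1
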