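"""Diagnostic metrics: confusion algebra, ROC/AUC, DeLong CIs, cutoff selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osascreen import (
    ConfusionTable,
    CutoffUnattainableError,
    accuracy_metrics,
    auc_confidence_interval,
    compare_auc_independent,
    confusion_from_scores,
    ratio_metrics_from_rates,
    reconstruct_confusion,
    roc_curve,
    select_cutoff,
)
from osascreen.metrics import round_half_away


class TestConfusionFromScores:
    def test_hand_tally(self):
        t = confusion_from_scores([0.02, 0.05, 0.80], [False, True, True], 0.04)
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 0, 0, 1)

    def test_score_equal_to_cutoff_is_negative(self):
        t = confusion_from_scores([0.04], [True], 0.04)
        assert (t.tp, t.fn) == (0, 1)

    def test_matches_naive_loop_on_random_fixture(self):
        rng = np.random.default_rng(3)
        scores = rng.random(1000)
        labels = rng.random(1000) < 0.4
        cutoff = 0.3
        tp = fn = fp = tn = 0
        for s, l in zip(scores, labels):
            if s > cutoff and l:
                tp += 1
            elif s <= cutoff and l:
                fn += 1
            elif s > cutoff:
                fp += 1
            else:
                tn += 1
        t = confusion_from_scores(scores, labels, cutoff)
        assert (t.tp, t.fn, t.fp, t.tn) == (tp, fn, fp, tn)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_from_scores([], [], 0.5)


class TestReconstruction:
    @pytest.mark.parametrize("args,expected", [
        ((216, 177, 0.966, 0.410), (171, 6, 23, 16)),   # full cohort, diagnostic outcome
        ((143, 129, 0.969, 0.50), (125, 4, 7, 7)),      # home-study (PSG III) stratum
        ((216, 99, 0.970, 0.274), (96, 3, 85, 32)),     # moderate/severe outcome
        ((100, 40, 1.0, 1.0), (40, 0, 0, 60)),          # perfect test
    ])
    def test_integer_tables_from_printed_summaries(self, args, expected):
        t = reconstruct_confusion(*args)
        assert (t.tp, t.fn, t.fp, t.tn) == expected

    def test_reproduces_inputs_within_rounding(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n_pos = int(rng.integers(5, 200))
            n_neg = int(rng.integers(5, 200))
            s, p = rng.random(), rng.random()
            t = reconstruct_confusion(n_pos + n_neg, n_pos, s, p)
            assert abs(t.tp / t.positives - s) <= 0.5 / n_pos + 1e-12
            assert abs(t.tn / t.negatives - p) <= 0.5 / n_neg + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(10, 0, 0.5, 0.5)
        with pytest.raises(ValueError):
            reconstruct_confusion(10, 5, 1.5, 0.5)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(86.57407 * 100, 0) == 8657  # guard against banker's rounding


class TestAccuracyMetrics:
    def test_printed_total_column_values(self):
        rep = accuracy_metrics(ConfusionTable(171, 6, 23, 16))
        assert rep.ppv.value == pytest.approx(0.8814, abs=5e-5)
        assert rep.npv.value == pytest.approx(0.7273, abs=5e-5)
        assert rep.accuracy.value == pytest.approx(0.8657, abs=5e-5)
        assert rep.lr_pos.value == pytest.approx(1.638, abs=5e-4)
        assert rep.lr_neg.value == pytest.approx(0.0826, abs=5e-5)
        assert rep.posttest_odds_pos.value == pytest.approx(7.43, abs=5e-3)

    def test_printed_moderate_severe_column(self):
        rep = accuracy_metrics(ConfusionTable(96, 3, 85, 32))
        assert rep.accuracy.value == pytest.approx(0.5926, abs=5e-5)
        assert rep.posttest_odds_neg.value == pytest.approx(0.0938, abs=5e-5)

    def test_perfect_table_degeneracies_flagged(self):
        rep = accuracy_metrics(ConfusionTable(10, 0, 0, 10))
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(rep, m).value == 1.0
        assert rep.lr_neg.value == 0.0 and rep.lr_neg.flag
        assert math.isinf(rep.dor.value) and rep.dor.flag

    def test_haldane_correction_definite(self):
        rep = accuracy_metrics(ConfusionTable(10, 0, 0, 10), zero_cell="haldane")
        assert math.isfinite(rep.dor.value) and rep.dor.value > 1
        assert rep.lr_neg.value > 0

    def test_ci_methods(self):
        t = ConfusionTable(171, 6, 23, 16)
        wilson = accuracy_metrics(t, ci_method="wilson")
        exact = accuracy_metrics(t, ci_method="clopper-pearson")
        for rep in (wilson, exact):
            assert rep.sensitivity.lo < rep.sensitivity.value < rep.sensitivity.hi
        assert wilson.sensitivity.lo != exact.sensitivity.lo
        with pytest.raises(ValueError):
            accuracy_metrics(t, ci_method="bootstrap")

    def test_rounded_rate_path_reproduces_printed_ratios(self):
        # ratio metrics derived from the printed (rounded) sens/spec
        r = ratio_metrics_from_rates(0.966, 0.410)
        assert round_half_away(r["dor"], 2) == 19.74
        r3 = ratio_metrics_from_rates(0.969, 0.50)
        assert round_half_away(r3["dor"], 2) == 31.26

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
    def test_metric_identities(self, tp, fn, fp, tn):
        rep = accuracy_metrics(ConfusionTable(tp, fn, fp, tn))
        assert rep.dor.value == pytest.approx(rep.lr_pos.value / rep.lr_neg.value, rel=1e-9)
        assert rep.posttest_odds_pos.value == pytest.approx(
            rep.pretest_odds.value * rep.lr_pos.value, rel=1e-9)
        assert rep.posttest_odds_neg.value == pytest.approx(
            rep.pretest_odds.value * rep.lr_neg.value, rel=1e-9)
        assert rep.accuracy.value == pytest.approx((tp + tn) / (tp + fn + fp + tn), rel=1e-12)
        assert rep.f_score.value == pytest.approx(2 * tp / (2 * tp + fp + fn), rel=1e-12)

    def test_reconstruction_composition_recovers_rates(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n_pos = int(rng.integers(10, 300))
            n_neg = int(rng.integers(10, 300))
            s, p = rng.random(), rng.random()
            rep = accuracy_metrics(reconstruct_confusion(n_pos + n_neg, n_pos, s, p))
            bound = 1 / (2 * min(n_pos, n_neg))
            assert abs(rep.sensitivity.value - s) <= bound + 1e-12
            assert abs(rep.specificity.value - p) <= bound + 1e-12


def mann_whitney_auc(scores, labels):
    """All-pairs count with half credit for ties (independent oracle)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert roc.auc == 1.0

    def test_constant_scores(self):
        roc = roc_curve([0.5] * 10, [True] * 5 + [False] * 5)
        assert roc.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trapezoid_equals_mann_whitney_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=30) / 7  # heavy ties
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        scores = rng.random(200)
        labels = rng.random(200) < 0.3
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_sensitivity_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(6)
        roc = roc_curve(rng.random(100), rng.random(100) < 0.5)
        assert (np.diff(roc.sensitivity) <= 0).all()
        assert (np.diff(roc.cutoffs) > 0).all()

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(80)
        labels = rng.random(80) < 0.4
        base = roc_curve(scores, labels)
        for f in (lambda x: 2 * x + 1, np.exp, lambda x: x**3):
            assert roc_curve(f(scores), labels).auc == pytest.approx(base.auc, abs=1e-12)

    def test_complement_symmetry_on_tie_free_data(self):
        rng = np.random.default_rng(12)
        scores = rng.permutation(100) / 100.0  # all distinct
        labels = rng.random(100) < 0.5
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.9], [True, True])


def delong_variance_loops(scores, labels):
    """Textbook DeLong variance with explicit double loops (oracle)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    m, n = len(pos), len(neg)
    psi = lambda x, y: 1.0 if x > y else (0.5 if x == y else 0.0)
    v10 = [sum(psi(x, y) for y in neg) / n for x in pos]
    v01 = [sum(psi(x, y) for x in pos) / m for y in neg]
    s10 = sum((v - sum(v10) / m) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - sum(v01) / n) ** 2 for v in v01) / (n - 1)
    return s10 / m + s01 / n


class TestAucConfidenceInterval:
    def test_delong_matches_loop_oracle(self):
        rng = np.random.default_rng(15)
        labels = rng.random(60) < 0.5
        scores = rng.normal(labels.astype(float), 1.0)
        roc = roc_curve(scores, labels)
        lo, hi = auc_confidence_interval(roc, "delong")
        var = delong_variance_loops(scores, labels)
        z = 1.959963984540054
        assert lo == pytest.approx(max(0.0, roc.auc - z * math.sqrt(var)), abs=1e-12)
        assert hi == pytest.approx(min(1.0, roc.auc + z * math.sqrt(var)), abs=1e-12)

    def test_delong_with_ties_matches_loop_oracle(self):
        rng = np.random.default_rng(16)
        labels = rng.random(50) < 0.5
        scores = rng.integers(0, 5, size=50).astype(float)
        roc = roc_curve(scores, labels)
        lo, hi = auc_confidence_interval(roc)
        var = delong_variance_loops(scores, labels)
        z = 1.959963984540054
        assert hi - lo == pytest.approx(2 * z * math.sqrt(var), abs=1e-12)

    def test_symmetric_noise_covers_half(self):
        rng = np.random.default_rng(17)
        labels = rng.random(2000) < 0.5
        scores = rng.random(2000)
        roc = roc_curve(scores, labels)
        lo, hi = auc_confidence_interval(roc)
        assert lo < 0.5 < hi

    def test_truncation_at_one(self):
        roc = roc_curve([0.9, 0.8, 0.7, 0.1, 0.2, 0.3],
                        [True, True, True, False, False, False])
        lo, hi = auc_confidence_interval(roc)
        assert hi <= 1.0

    def test_hanley_mcneil_option(self):
        rng = np.random.default_rng(18)
        labels = rng.random(100) < 0.5
        scores = rng.normal(labels.astype(float), 1.0)
        roc = roc_curve(scores, labels)
        d = auc_confidence_interval(roc, "delong")
        h = auc_confidence_interval(roc, "hanley-mcneil")
        assert d != h
        assert all(0 <= v <= 1 for v in (*d, *h))


class TestCompareAuc:
    def test_identical_inputs_give_p_one(self):
        rng = np.random.default_rng(19)
        labels = rng.random(40) < 0.5
        scores = rng.normal(labels.astype(float), 1.0)
        roc = roc_curve(scores, labels)
        assert compare_auc_independent(roc, roc) == pytest.approx(1.0)

    def test_matches_hand_computed_z(self):
        rng = np.random.default_rng(20)
        l1 = rng.random(50) < 0.5
        s1 = rng.normal(l1.astype(float), 1.0)
        l2 = rng.random(70) < 0.5
        s2 = rng.normal(l2 * 0.3, 1.0)
        r1, r2 = roc_curve(s1, l1), roc_curve(s2, l2)
        v = delong_variance_loops(s1, l1) + delong_variance_loops(s2, l2)
        from scipy.stats import norm
        expected = 2 * norm.sf(abs(r1.auc - r2.auc) / math.sqrt(v))
        assert compare_auc_independent(r1, r2) == pytest.approx(expected, abs=1e-12)

    def test_type_one_error_rate_near_nominal(self):
        # no true AUC difference: rejection rate should sit at alpha = 0.05
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            def sample():
                labels = np.repeat([True, False], 100)
                scores = rng.normal(labels.astype(float), 1.5)
                return roc_curve(scores, labels)
            if compare_auc_independent(sample(), sample()) < 0.05:
                rejections += 1
        rate = rejections / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 2 * se


def select_cutoff_scan_oracle(roc, min_sens):
    best = None
    for c, s, f in zip(roc.cutoffs, roc.sensitivity, roc.fpr):
        if s >= min_sens:
            key = (1 - f, c)
            if best is None or key > best:
                best = key
    if best is None:
        raise ValueError
    return best[1]


class TestSelectCutoff:
    def test_constraint_forces_middle_cutoff(self):
        # sens 1.0 / 0.97 / 0.90 at cutoffs 0.02 / 0.04 / 0.10
        scores = np.concatenate([
            np.full(3, 0.04), np.full(7, 0.10), np.full(90, 0.5),  # positives
            np.full(5, 0.02), np.full(5, 0.04)])                   # negatives
        labels = np.array([True] * 100 + [False] * 10)
        roc = roc_curve(scores, labels)
        got = select_cutoff(roc, 0.95)
        assert got == pytest.approx(0.04)
        t = confusion_from_scores(scores, labels, got)
        assert t.tp / t.positives >= 0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 20, size=200) / 19
        labels = rng.random(200) < 0.6
        roc = roc_curve(scores, labels)
        assert select_cutoff(roc, 0.9) == select_cutoff_scan_oracle(roc, 0.9)

    def test_unattainable_sensitivity_errors(self):
        roc = roc_curve([0.1, 0.9], [False, True])
        with pytest.raises(CutoffUnattainableError):
            select_cutoff(roc, 1.01)
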