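import numpy as np
import pandas as pd
import pytest

from plasmacna import coverage, diagnostics, genome
from plasmacna.diagnostics import (confusion_metrics, roc, wilcoxon_ranksum,
                                   wilcoxon_signed_rank, youden_cutoff)


def youden_oracle(scores, labels):
    """Exhaustive enumeration with the documented tie rules."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best_key, best_c = None, None
    for c in np.unique(scores):
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        key = (sens + spec - 1, spec, -c)
        if best_key is None or key > best_key:
            best_key, best_c = key, float(c)
    return best_c


class TestArmCalls:
    def _bins(self):
        kt = genome.Karyotype(pd.DataFrame({
            "chrom": ["c"], "length": [40_000_000],
            "centromere_mid": [20_000_000]}))
        return genome.make_bins(kt, 200_000)  # 100 p bins + 100 q bins

    def test_all_zero_no_calls(self):
        bins = self._bins()
        zp = coverage.ZProfile("s", np.zeros(200), np.zeros(200),
                               np.ones(200, bool))
        calls = diagnostics.arm_calls(zp, bins)
        assert all(c.direction == "none" for c in calls)

    def test_stouffer_aggregation(self):
        bins = self._bins()
        z = np.zeros(200)
        z[100:] = 0.5  # q arm: 0.5 * 100 / sqrt(100) = 5
        zp = coverage.ZProfile("s", z, np.zeros(200), np.ones(200, bool))
        calls = {(c.chrom, c.arm): c for c in diagnostics.arm_calls(zp, bins)}
        assert calls[("c", "q")].aggregate_z == pytest.approx(5.0)
        assert calls[("c", "q")].direction == "gain"
        assert calls[("c", "p")].direction == "none"

    def test_loss_direction(self):
        bins = self._bins()
        z = np.zeros(200)
        z[:100] = -0.5
        zp = coverage.ZProfile("s", z, np.zeros(200), np.ones(200, bool))
        calls = {(c.chrom, c.arm): c for c in diagnostics.arm_calls(zp, bins)}
        assert calls[("c", "p")].direction == "loss"

    def test_sparse_arm_low_confidence(self):
        bins = self._bins()
        z = np.full(200, np.nan)
        z[100:] = 1.0
        zp = coverage.ZProfile("s", z, np.zeros(200), np.ones(200, bool))
        calls = {(c.chrom, c.arm): c for c in diagnostics.arm_calls(zp, bins)}
        assert calls[("c", "p")].low_confidence
        assert calls[("c", "p")].direction == "none"


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        res = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_multisets_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_ranksum([1.0, 1.0], [1.0, 1.0])
        assert res.p == 1.0

    def test_same_distribution_symmetric(self):
        res = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0, abs=0.05)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            if wilcoxon_ranksum(x, y).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestWilcoxonSignedRank:
    def test_all_negative_shifts_exact(self):
        pre = np.arange(1.0, 17.0)
        # post = pre - 1: every difference positive, smallest attainable p
        res = wilcoxon_signed_rank(pre, pre - 1.0)
        assert res.p == pytest.approx(2 * 2.0 ** -16)

    def test_identical_pairs(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestRoc:
    def test_perfect_separation(self):
        res = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], compute_ci=False)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_rank_identity_hand_case(self):
        res = roc([1, 2, 3, 4], [0, 0, 1, 1], compute_ci=False)
        assert res.auc == 1.0
        res = roc([1, 2, 3, 4], [0, 1, 0, 1], compute_ci=False)
        assert res.auc == 0.75  # U/(n1*n2) by hand

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=200)
        res = roc(scores, labels, compute_ci=False)
        assert 0.4 < res.auc < 0.6

    def test_matches_sklearn_trapezoid_oracle(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(size=n), 1)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            res = roc(scores, labels, compute_ci=False)
            assert res.auc == pytest.approx(roc_auc_score(labels, scores),
                                            abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1], compute_ci=False)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        res = roc(scores, labels, n_boot=500, seed=9)
        lo, hi = res.auc_ci
        assert lo <= res.auc <= hi
        assert hi - lo < 0.5

    def test_ci_deterministic_under_seed(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = [0, 0, 1, 0, 1, 1]
        a = roc(scores, labels, n_boot=200, seed=5)
        b = roc(scores, labels, n_boot=200, seed=5)
        assert a.auc_ci == b.auc_ci


class TestYouden:
    def test_separated_returns_smallest_positive_score(self):
        c = youden_cutoff([1, 2, 10, 11], [0, 0, 1, 1])
        assert c == 10

    def test_hand_enumeration(self):
        c = youden_cutoff([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        assert c == youden_oracle([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        assert c == 0.4  # J ties at 0.2 and 0.4; higher specificity wins

    def test_oracle_agreement_random(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert youden_cutoff(scores, labels) == youden_oracle(scores, labels)

    def test_j_is_global_max(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = (scores + rng.normal(size=50) > 0).astype(int)
        c = youden_cutoff(scores, labels)
        pred = scores >= c
        j_best = ((pred & (labels == 1)).sum() / (labels == 1).sum()
                  + (~pred & (labels == 0)).sum() / (labels == 0).sum() - 1)
        for other in np.unique(scores):
            pred = scores >= other
            j = ((pred & (labels == 1)).sum() / (labels == 1).sum()
                 + (~pred & (labels == 0)).sum() / (labels == 0).sum() - 1)
            assert j <= j_best + 1e-12


class TestConfusionMetrics:
    def test_high_burden_histology_row(self):
        # tp=36, fn=5, tn=11, fp=0
        m = confusion_metrics(36, 0, 11, 5).rounded()
        assert m["sensitivity"] == 0.88
        assert m["specificity"] == 1.0
        assert m["ppv"] == 1.0
        assert m["npv"] == 0.69
        assert m["accuracy"] == 0.90

    def test_intermediate_burden_histology_row(self):
        # tp=10, fn=12, tn=9, fp=2
        m = confusion_metrics(10, 2, 9, 12).rounded()
        assert m["accuracy"] == 0.58
        assert m["ppv"] == 0.83
        assert m["npv"] == 0.43

    def test_degenerate_tiny(self):
        m = confusion_metrics(0, 0, 1, 1)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.accuracy == 0.5
        assert m.ppv is None  # zero denominator -> missing, not exception

    def test_identity_accuracy_decomposition(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            m = confusion_metrics(int(tp), int(fp), int(tn), int(fn))
            n = tp + fp + tn + fn
            recon = (m.sensitivity * (tp + fn) + m.specificity * (tn + fp)) / n
            assert m.accuracy == pytest.approx(recon)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 1)
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestEvaluateGroup:
    def _cohort(self):
        rng = np.random.default_rng(11)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(30)],
            "tfx": np.r_[rng.uniform(0.05, 0.4, 15), rng.uniform(0, 0.002, 15)],
            "group": ["tumor"] * 15 + ["control"] * 15,
        })

    def test_separated_cohort_auc(self):
        res = diagnostics.evaluate_group(
            self._cohort(), 'group == "tumor"', 'group == "control"',
            n_boot=200, seed=1)
        assert res.auc >= 0.95

    def test_overlapping_definitions_rejected(self):
        cohort = self._cohort()
        with pytest.raises(ValueError, match="overlap"):
            diagnostics.evaluate_group(cohort, 'group == "tumor"',
                                       'tfx >= 0', n_boot=100)

    def test_empty_side_rejected(self):
        cohort = self._cohort()
        with pytest.raises(ValueError):
            diagnostics.evaluate_group(cohort, 'group == "nope"',
                                       'group == "control"', n_boot=100)


class TestPairedReport:
    def test_identical_pairs(self):
        pairs = pd.DataFrame({"tfx_pre": [1.0] * 6, "tfx_post": [1.0] * 6})
        with pytest.warns(UserWarning):
            out = diagnostics.paired_tfx_report(pairs)
        assert out["p"] == 1.0
        assert out["median_change"] == 0.0

    def test_tenfold_reduction_medians(self):
        pre = np.arange(1.0, 17.0)
        pairs = pd.DataFrame({"tfx_pre": pre, "tfx_post": pre / 10})
        out = diagnostics.paired_tfx_report(pairs)
        assert out["pre_median"] == 8.5
        assert out["post_median"] == pytest.approx(0.85)
        assert out["p"] < 0.001
        assert out["pre_range"] == (1.0, 16.0)

    def test_too_few_pairs_descriptive_only(self):
        pairs = pd.DataFrame({"tfx_pre": [1, 2, 3.0], "tfx_post": [0.5, 1, 2.0]})
        with pytest.warns(UserWarning):
            out = diagnostics.paired_tfx_report(pairs)
        assert out["p"] is None
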