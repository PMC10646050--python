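"""Metric formulas, BG exclusion, and the rank-sum spectral test."""

from itertools import combinations

import numpy as np
import pytest

from hsibrain import (
    PixelDataset,
    channelwise_wilcoxon,
    class_mean_std,
    compute_metrics,
    macro_f1_no_bg,
)
from hsibrain.metrics import confusion_counts, rank_sum_pvalue


class TestComputeMetrics:
    def test_perfect_prediction_scores_100(self):
        gt = np.array([[1, 2], [3, 4]])
        report = compute_metrics(gt, gt)
        assert report.macro_f1 == 100.0 and report.oa == 100.0
        assert all(v == 100.0 for v in report.sensitivity.values())
        assert all(v == 100.0 for v in report.specificity.values())

    def test_f1_from_counts(self):
        # TP=8, FP=2, FN=2 -> F1 = 16/20 = 80%
        gt = np.array([1] * 10 + [2] * 10)
        pred = np.array([1] * 8 + [2] * 2 + [2] * 8 + [1] * 2)
        c = confusion_counts(pred, gt, positive=1)
        assert (c.tp, c.fp, c.fn) == (8, 2, 2)
        assert c.f1 == pytest.approx(80.0)

    def test_unlabelled_pixels_excluded(self):
        gt = np.array([[0, 1], [0, 2]])
        pred = np.array([[4, 1], [3, 2]])  # wrong only on unlabelled pixels
        report = compute_metrics(pred, gt)
        assert report.oa == 100.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        report = compute_metrics(pred.reshape(20, 10), gt.reshape(20, 10))

        f1s = {}
        for code in (1, 2, 3):
            tp = sum(1 for p, g in zip(pred, gt) if p == code and g == code)
            fp = sum(1 for p, g in zip(pred, gt) if p == code and g != code)
            fn = sum(1 for p, g in zip(pred, gt) if p != code and g == code)
            f1s[code] = 100.0 * 2 * tp / (2 * tp + fp + fn)
        assert report.macro_f1 == pytest.approx(np.mean(list(f1s.values())))
        assert report.oa == pytest.approx(100.0 * np.mean(pred == gt))

    def test_macro_f1_excludes_background(self):
        gt = np.array([1, 2, 3, 4, 4, 4])
        pred_bg_wrong = np.array([1, 2, 3, 1, 1, 1])  # only BG misclassified
        # BG errors surface as tissue false positives, not via a BG F1 term:
        # NT picks up 3 false positives, TT and BV stay perfect
        assert macro_f1_no_bg(pred_bg_wrong, gt) == pytest.approx(
            (40.0 + 100.0 + 100.0) / 3
        )
        # whereas OA counts the BG mistakes directly
        assert compute_metrics(pred_bg_wrong, gt).oa == pytest.approx(50.0)

    def test_macro_f1_invariant_to_tissue_relabelling(self):
        rng = np.random.default_rng(1)
        gt = rng.integers(1, 4, 300)
        pred = rng.integers(1, 4, 300)
        swap = {1: 2, 2: 3, 3: 1}
        gt2 = np.vectorize(swap.get)(gt)
        pred2 = np.vectorize(swap.get)(pred)
        assert macro_f1_no_bg(pred, gt) == pytest.approx(macro_f1_no_bg(pred2, gt2))

    def test_no_labelled_pixels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones((2, 2)), np.zeros((2, 2)))


def _exact_ranksum_pvalue(a, b):
    """Enumerate all label assignments of the pooled sample (no ties)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    observed = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2
    stats = []
    for grp in combinations(range(len(pooled)), n_a):
        stats.append(sum(ranks[pooled[i]] for i in grp))
    stats = np.array(stats)
    p = np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
    return p


class TestChannelwiseWilcoxon:
    def test_identical_groups_never_significant(self):
        rng = np.random.default_rng(2)
        group = rng.random((30, 5))
        pvals, sig = channelwise_wilcoxon(group, group.copy())
        assert not sig.any()
        assert (pvals > 0.9).all()

    def test_shifted_channel_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 0.05, (50, 4))
        b = rng.normal(0.5, 0.05, (50, 4))
        b[:, 2] += 1.0  # shift far beyond the noise at one channel
        pvals, sig = channelwise_wilcoxon(a, b, alpha=0.05)
        assert sig[2]
        assert pvals[2] < 1e-6

    @pytest.mark.parametrize("n_a,n_b", [(4, 4), (5, 6), (8, 7)])
    def test_exact_small_sample_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(4)
        a = rng.permutation(np.arange(1.0, n_a + n_b + 1))[:n_a]
        b = np.setdiff1d(np.arange(1.0, n_a + n_b + 1), a)
        assert rank_sum_pvalue(a, b) == pytest.approx(
            _exact_ranksum_pvalue(a, b), abs=1e-9
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            channelwise_wilcoxon(np.ones((1, 3)), np.ones((5, 3)))


class TestClassMeanStd:
    def test_single_pixel_mean_is_pixel_std_zero(self):
        ds = PixelDataset(
            np.array([[0.2, 0.4, 0.8]]), np.array([2]), np.array(["p"])
        )
        out = class_mean_std(ds, 2)
        np.testing.assert_allclose(out["mean"], [0.2, 0.4, 0.8])
        np.testing.assert_allclose(out["std"], 0.0)
        np.testing.assert_allclose(out["mean_absorbance"], -np.log10([0.2, 0.4, 0.8]))

    def test_duplicated_dataset_invariant(self):
        rng = np.random.default_rng(5)
        spectra = rng.random((10, 6)) + 0.05
        labels = np.full(10, 3)
        ds = PixelDataset(spectra, labels, np.array(["p"] * 10))
        doubled = PixelDataset(
            np.vstack([spectra, spectra]),
            np.r_[labels, labels],
            np.array(["p"] * 20),
        )
        a, b = class_mean_std(ds, 3), class_mean_std(doubled, 3)
        np.testing.assert_allclose(a["mean"], b["mean"])
        np.testing.assert_allclose(a["std"], b["std"])

    def test_matches_bruteforce(self, phantom_pixels):
        out = class_mean_std(phantom_pixels, 1)
        sel = phantom_pixels.spectra[phantom_pixels.labels == 1]
        np.testing.assert_allclose(out["mean"], sel.mean(axis=0))
        np.testing.assert_allclose(out["std"], sel.std(axis=0))

    def test_missing_class_rejected(self, phantom_pixels):
        with pytest.raises(ValueError):
            class_mean_std(phantom_pixels.subset(phantom_pixels.labels == 1), 2)
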