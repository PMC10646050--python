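"""Evaluation metrics and per-channel spectral statistics.

Per-class one-vs-rest confusion counts feed the standard metrics::

    F1_i        = 2 TP / (2 TP + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    OA          = fraction of labelled pixels classified correctly

Macro F1 averages F1 over the three tissue classes NT, TT and BV only: the
background class is deliberately excluded so that a map which nails the
(easy, abundant) background cannot mask poor tumour delineation. All
metrics are reported as percentages.

The spectral characterization compares two pixel populations channel by
channel with a two-sided Wilcoxon rank-sum (Mann-Whitney) test at the 5%
level. Group sizes are generally unequal, so the unpaired form is the only
applicable one; small samples without ties use the exact null distribution,
larger ones the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BG, BV, NT, TT, CLASS_NAMES, LabelMap, PixelDataset
from .preprocess import to_absorbance

TISSUE_CODES = (NT, TT, BV)  # macro F1 averages over these only
EXACT_MAX_COMBINED_N = 16  # exact rank-sum enumeration below this total


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

# a class absent from both truth and prediction is vacuously perfect
    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 100.0 * 2 * self.tp / denom if denom else 100.0

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 100.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else 100.0


@dataclass
class MetricReport:
    """Percent-scale summary of one prediction map against ground truth."""

    macro_f1: float
    oa: float
    per_class: dict[str, ConfusionCounts]

    @property
    def sensitivity(self) -> dict[str, float]:
        return {k: c.sensitivity for k, c in self.per_class.items()}

    @property
    def specificity(self) -> dict[str, float]:
        return {k: c.specificity for k, c in self.per_class.items()}

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "oa": self.oa,
            "f1": {k: c.f1 for k, c in self.per_class.items()},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_counts(
    pred: np.ndarray, gt: np.ndarray, positive: int
) -> ConfusionCounts:
    """One-vs-rest counts for one class over labelled pixels."""
    p = pred == positive
    g = gt == positive
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def compute_metrics(pred: np.ndarray | LabelMap, gt: np.ndarray | LabelMap) -> MetricReport:
    """Evaluate a predicted class map against a (possibly sparse) label map.

    Unlabelled ground-truth pixels (code 0) are excluded from every count.
    """
    pred = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    gt = gt.labels if isinstance(gt, LabelMap) else np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth geometries differ")
    mask = gt > 0
    if not mask.any():
        raise ValueError("no labelled pixels to evaluate")
    p, g = pred[mask].ravel(), gt[mask].ravel()
    per_class = {
        CLASS_NAMES[code]: confusion_counts(p, g, code)
        for code in (NT, TT, BV, BG)
    }
    macro = float(np.mean([per_class[CLASS_NAMES[c]].f1 for c in TISSUE_CODES]))
    oa = 100.0 * float(np.mean(p == g))
    return MetricReport(macro_f1=macro, oa=oa, per_class=per_class)


def macro_f1_no_bg(pred: np.ndarray, gt: np.ndarray) -> float:
    """Macro F1 over NT/TT/BV on flat label vectors (BG excluded)."""
    pred, gt = np.asarray(pred).ravel(), np.asarray(gt).ravel()
    mask = gt > 0
    if not mask.any():
        raise ValueError("no labelled pixels")
    p, g = pred[mask], gt[mask]
    return float(np.mean([confusion_counts(p, g, c).f1 for c in TISSUE_CODES]))


def rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration for small untied samples, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_COMBINED_N and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def channelwise_wilcoxon(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel two-sided rank-sum comparison of two pixel populations.

    Parameters
    ----------
    group_a, group_b : ndarray, (n_pixels, n_channels)
        Spectra of the two populations (1-D inputs are treated as a single
        channel).
    alpha : float
        Significance level for the rejection mask.

    Returns
    -------
    pvalues : ndarray, (n_channels,)
    significant : ndarray of bool, (n_channels,) — ``pvalues < alpha``
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with equal channel counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 pixels")
    pvalues = np.array(
        [rank_sum_pvalue(a[:, ch], b[:, ch]) for ch in range(a.shape[1])]
    )
    return pvalues, pvalues < alpha


def class_mean_std(
    pixels: PixelDataset, class_code: int
) -> dict[str, np.ndarray]:
    """Per-channel mean/std of one class, in reflectance and absorbance."""
    mask = pixels.labels == class_code
    if not mask.any():
        raise ValueError(f"class {class_code} has no pixels")
    spectra = pixels.spectra[mask]
    absorb = to_absorbance(spectra)
    return {
        "mean": spectra.mean(axis=0),
        "std": spectra.std(axis=0),
        "mean_absorbance": absorb.mean(axis=0),
        "std_absorbance": absorb.std(axis=0),
    }
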