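"""Base-pair-resolution evaluation of denoised tracks and peak probabilities.

Regression quality (denoised vs clean coverage) is measured with Pearson
correlation, Spearman correlation and MSE; classification quality (per-base
peak probabilities vs binary labels) with AUPRC and AUROC over the full range
of thresholds. All metrics can be computed genome-wide and stratified into a
region mask and its complement (e.g. within vs outside accessible-chromatin
peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .genomic_io import DenseTrack, IntervalSet

__all__ = [
    "RegressionMetrics",
    "EvalReport",
    "track_regression_metrics",
    "classification_metrics",
    "compare_eval",
]


@dataclass(frozen=True)
class RegressionMetrics:
    """Pearson/Spearman/MSE over one stratum; correlations are None when a
    vector is constant (undefined rather than NaN)."""

    pearson: float | None
    spearman: float | None
    mse: float
    n: int


@dataclass(frozen=True)
class EvalReport:
    """Regression metrics per stratum plus classification metrics."""

    genome: RegressionMetrics
    within_mask: RegressionMetrics | None
    outside_mask: RegressionMetrics | None
    auprc: float | None
    auroc: float | None


def _regression(pred: np.ndarray, ref: np.ndarray) -> RegressionMetrics:
    mse = float(np.mean((pred - ref) ** 2))
    if pred.std() == 0 or ref.std() == 0:
        return RegressionMetrics(None, None, mse, pred.size)
    pearson = float(stats.pearsonr(pred, ref).statistic)
    spearman = float(stats.spearmanr(pred, ref).statistic)
    return RegressionMetrics(pearson, spearman, mse, pred.size)


def track_regression_metrics(
    pred: DenseTrack, ref: DenseTrack, mask: IntervalSet | None = None
) -> RegressionMetrics:
    """Pearson, Spearman (average ranks on ties) and MSE of pred vs ref.

    With a mask, metrics cover only the masked bases; otherwise all bases.
    """
    if pred.layout != ref.layout:
        raise ValueError("tracks must share a layout")
    if mask is None:
        return _regression(pred.flatten(), ref.flatten())
    masks = mask.mask_arrays(pred.layout)
    sel_pred = np.concatenate([pred[c][masks[c]] for c, _ in pred.layout])
    sel_ref = np.concatenate([ref[c][masks[c]] for c, _ in pred.layout])
    if sel_pred.size == 0:
        raise ValueError("mask selects no bases")
    return _regression(sel_pred, sel_ref)


def classification_metrics(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """(AUPRC, AUROC) of per-base scores against binary labels.

    AUROC follows the tie-corrected Mann-Whitney formulation; AUPRC is the
    step integration of the precision-recall curve over the distinct score
    thresholds (no interpolation between tied scores).
    """
    scores = np.asarray(scores).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels.sum()
    if pos == 0 or pos == labels.size:
        raise ValueError("labels must contain both classes")
    auprc = float(average_precision_score(labels, scores))
    auroc = float(roc_auc_score(labels, scores))
    return auprc, auroc


def _report(
    pred: DenseTrack,
    ref: DenseTrack,
    labels: IntervalSet | None,
    mask: IntervalSet | None,
) -> EvalReport:
    genome = track_regression_metrics(pred, ref)
    within = outside = None
    if mask is not None:
        within = track_regression_metrics(pred, ref, mask)
        masks = mask.mask_arrays(pred.layout)
        sel_p = np.concatenate([pred[c][~masks[c]] for c, _ in pred.layout])
        sel_r = np.concatenate([ref[c][~masks[c]] for c, _ in pred.layout])
        outside = _regression(sel_p, sel_r)
    auprc = auroc = None
    if labels is not None:
        lab = np.concatenate(
            [m.astype(np.float64) for m in
             (labels.mask_arrays(pred.layout)[c] for c, _ in pred.layout)]
        )
        if 0 < lab.sum() < lab.size:
            auprc, auroc = classification_metrics(pred.flatten(), lab)
    return EvalReport(genome, within, outside, auprc, auroc)


def compare_eval(
    noisy: DenseTrack,
    denoised: DenseTrack,
    ref: DenseTrack,
    labels: IntervalSet | None = None,
    mask: IntervalSet | None = None,
) -> tuple[EvalReport, EvalReport]:
    """Paired evaluation of the noisy and denoised tracks against the clean
    reference, on identical strata. When ``labels`` is given, each track is
    also scored as a peak classifier against those labels (for the noisy track
    this is the raw-coverage-as-score baseline)."""
    return (
        _report(noisy, ref, labels, mask),
        _report(denoised, ref, labels, mask),
    )
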