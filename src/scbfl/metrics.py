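"""Classifier evaluation from first principles: confusion counts, ROC and
precision-recall curves, and their areas.

Predictions are positive when score >= threshold, consistently across every
function here. AUC-ROC is the trapezoidal area over (FPR, TPR) and equals
the probability that a positive sample outranks a negative one (ties
counting one half); AUC-PR uses the average-precision (right-step)
convention, since trapezoidal interpolation of precision is biased.

Also here: upload accounting — the fraction of weight parameters a sparse
gradient actually communicates, the simulator's "trans-information" proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ProcessedGradient
from .nn import ModelParams

__all__ = [
    "CurvePoints",
    "confusion_counts",
    "curve_points",
    "auc",
    "auc_roc",
    "auc_pr",
    "upload_fraction",
    "UploadAccountant",
    "write_curve_csv",
]


@dataclass
class CurvePoints:
    """ROC / PR operating points swept over descending score thresholds.

    The first point is the all-negative operating point (threshold above
    every score: FPR = TPR = 0, precision defined as 1) and the last is the
    all-positive point (FPR = TPR = recall = 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray


def _check_scores_labels(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels


def confusion_counts(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) at one cutoff; positive prediction iff score >= threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    pos = labels == 1.0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, fn, tn


def curve_points(scores: np.ndarray, labels: np.ndarray) -> CurvePoints:
    """Sweep every distinct score as a threshold (descending) and compute
    TPR, FPR, precision and recall at each, with sentinel endpoints.

    Raises on single-class labels, where the areas are undefined.
    """
    scores, labels = _check_scores_labels(scores, labels)
    P = int(labels.sum())
    N = labels.size - P
    if P == 0 or N == 0:
        raise ValueError("both classes must be present to build a curve")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1.0 - y)
    # keep the last index of each tie group: counts there reflect the
    # >=-threshold rule at that distinct score
    last = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]

    tp = np.r_[0.0, tp_cum[last], float(P)]
    fp = np.r_[0.0, fp_cum[last], float(N)]
    thresholds = np.r_[np.inf, s[last], -np.inf]

    tpr = tp / P
    fpr = fp / N
    predicted = tp + fp
    precision = np.ones_like(tp)
    nz = predicted > 0
    precision[nz] = tp[nz] / predicted[nz]

    return CurvePoints(
        thresholds=thresholds, tpr=tpr, fpr=fpr, precision=precision, recall=tpr.copy()
    )


def auc(points: CurvePoints, which: str) -> float:
    """Area under the ROC (trapezoid over FPR) or PR (right-step over
    recall increments, i.e. average precision) curve."""
    if which == "roc":
        return float(np.trapezoid(points.tpr, points.fpr))
    if which == "pr":
        d_recall = np.diff(points.recall)
        return float(np.sum(d_recall * points.precision[1:]))
    raise ValueError(f"which must be 'roc' or 'pr', got {which!r}")


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    return auc(curve_points(scores, labels), "roc")


def auc_pr(scores: np.ndarray, labels: np.ndarray) -> float:
    return auc(curve_points(scores, labels), "pr")


def upload_fraction(upload: ProcessedGradient, model: ModelParams) -> float:
    """Fraction of the model's weight entries the sparse upload carries
    (nonzeros of G-tilde over total weight parameters)."""
    for d, W in zip(upload.deltas, model.weights):
        if d.shape != W.shape:
            raise ValueError("upload and model shapes disagree")
    return upload.n_uploaded_entries / model.n_weight_params


class UploadAccountant:
    """Running totals of communicated parameter entries — backs the
    trans-information comparison between sparse and full uploads."""

    def __init__(self) -> None:
        self.cumulative_entries = 0
        self.per_loop: list[int] = []

    def record(self, entries: int) -> None:
        self.cumulative_entries += int(entries)
        self.per_loop.append(int(entries))


def write_curve_csv(points: CurvePoints, path: str | Path) -> None:
    pd.DataFrame(
        {
            "threshold": points.thresholds,
            "tpr": points.tpr,
            "fpr": points.fpr,
            "precision": points.precision,
            "recall": points.recall,
        }
    ).to_csv(path, index=False)
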