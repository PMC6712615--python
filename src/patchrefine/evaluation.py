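"""Classification metrics and patch-to-slice vote fusion.

ACA (overall correct classification rate), per-class accuracies, confusion
matrices, and the standard precision / recall / F-measure

    Precision = TP / (TP + FP),  Recall = TP / (TP + FN),
    F = 2 * Precision * Recall / (Precision + Recall),

with the convention that a zero denominator yields 0.  Slide-level ("slice")
predictions are the majority vote of patch-level argmax predictions, ties
broken by the highest mean probability over the tied classes, then by the
lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "confusion",
    "aca",
    "precision_recall_f",
    "classification_metrics",
    "slice_vote",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class ClassificationMetrics:
    aca: float
    per_class_acc: np.ndarray
    precision: np.ndarray  # per class
    recall: np.ndarray
    f_measure: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    macro_f: float
    micro_f: float


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> ConfusionMatrix:
    """counts[t][p] = number of samples with true class t predicted as p."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have the same length")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= n_classes):
        raise ValueError("label outside [0, n_classes)")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def aca(matrix: ConfusionMatrix) -> float:
    """Overall correct classification rate: trace / total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(matrix.counts) / matrix.total)


def precision_recall_f(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """Set precision, recall and their harmonic mean (0 on empty denominators)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def classification_metrics(matrix: ConfusionMatrix) -> ClassificationMetrics:
    """Per-class and averaged metrics from a confusion matrix.

    Micro averaging pools TP/FP/FN over classes (for single-label multiclass
    data micro-recall equals ACA); macro averaging is the unweighted mean of
    the per-class values.
    """
    c = matrix.counts
    K = matrix.n_classes
    tp = np.diag(c).astype(np.int64)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    prec = np.zeros(K)
    rec = np.zeros(K)
    f = np.zeros(K)
    for k in range(K):
        prec[k], rec[k], f[k] = precision_recall_f(int(tp[k]), int(fp[k]), int(fn[k]))
    row = c.sum(axis=1)
    per_class = np.divide(tp, row, out=np.zeros(K, dtype=float), where=row > 0)
    _, _, micro_f = precision_recall_f(int(tp.sum()), int(fp.sum()), int(fn.sum()))
    return ClassificationMetrics(
        aca=aca(matrix),
        per_class_acc=per_class,
        precision=prec,
        recall=rec,
        f_measure=f,
        tp=tp,
        fp=fp,
        fn=fn,
        macro_f=float(f.mean()),
        micro_f=micro_f,
    )


def slice_vote(patch_probs_by_slide: Dict[str, np.ndarray]) -> Dict[str, int]:
    """Slide-level label by majority vote of patch argmax predictions.

    ``patch_probs_by_slide`` maps slide id -> (n_patches, K) probability
    array.  Ties in vote count are broken by the highest mean probability
    among the tied classes, then by the lowest class index; the result is
    deterministic and independent of patch order.
    """
    out = {}
    for sid, probs in patch_probs_by_slide.items():
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[0] == 0:
            raise ValueError(f"slide {sid!r} has no patch predictions")
        K = probs.shape[1]
        votes = np.bincount(probs.argmax(axis=1), minlength=K)
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if len(tied) == 1:
            out[sid] = int(tied[0])
        else:
            mean_p = probs.mean(axis=0)[tied]
            # argmax returns the first (lowest-index) maximum: final tie-break
            out[sid] = int(tied[np.argmax(mean_p)])
    return out
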