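"""Classification and survival-discrimination metrics.

Positive class throughout is *Alive* (5-year survivor), matching the layout
of the study's confusion matrices. Scores are survival probabilities: a
record is predicted Alive when its score meets the threshold. AUC is the
trapezoidal area under the threshold-swept ROC curve and equals the
Mann-Whitney probability with ties counted one half; the operating
threshold may be chosen by Youden's J = sensitivity + specificity - 1.
Harrell's C-index handles right censoring through the comparable-pair rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "EvaluationReport",
    "confusion_matrix",
    "accuracy",
    "roc_curve",
    "auc",
    "youden_threshold",
    "harrell_c_index",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with Alive as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        out = np.where(arr == "Alive", 1, np.where(arr == "Dead", 0, -1))
        if (out < 0).any():
            raise ValueError("labels must be 'Alive'/'Dead' or 0/1")
        return out
    out = arr.astype(np.int64)
    if not np.isin(out, (0, 1)).all():
        raise ValueError("binary labels must be 0/1")
    return out


def confusion_matrix(predicted, truth) -> ConfusionMatrix:
    pred = _as_binary(predicted)
    true = _as_binary(truth)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predicted and truth must be equal-length, nonempty")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


@dataclass(frozen=True)
class RocCurve:
    """Operating points (fpr, tpr) with thresholds, from lax to strict."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def roc_curve(scores, truth) -> RocCurve:
    """Threshold sweep over the unique scores (ties grouped).

    The rule "predict positive iff score >= threshold" is evaluated at every
    unique score plus a strict sentinel above the maximum, so the curve runs
    from (0, 0) to (1, 1). The sentinel operating point carries threshold
    +inf.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    if s.shape != y.shape:
        raise ValueError("scores and truth must be equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)  # ascending
    thresholds = np.concatenate([[np.inf], uniq[::-1]])
    fpr, tpr = [], []
    for thr in thresholds:
        pred = s >= thr
        tpr.append(np.sum(pred & (y == 1)) / n_pos)
        fpr.append(np.sum(pred & (y == 0)) / n_neg)
    return RocCurve(np.asarray(fpr), np.asarray(tpr), thresholds)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area; equals the Mann-Whitney U probability with ties 1/2."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_threshold(scores, truth) -> float:
    """Observed score maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the smallest qualifying threshold, so a perfectly
    separating score set returns the smallest score achieving J = 1.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best_thr, best_j = None, -np.inf
    for thr in np.unique(s):  # ascending; strict > keeps the first maximizer
        pred = s >= thr
        j = (
            np.sum(pred & (y == 1)) / n_pos
            - np.sum(pred & (y == 0)) / n_neg
        )
        if j > best_j + 1e-12:
            best_thr, best_j = thr, j
    return float(best_thr)


def harrell_c_index(risk, time, event) -> float:
    """Harrell's concordance for right-censored data.

    A pair (i, j) is comparable when the strictly earlier time is an
    observed event (time_i < time_j with event_i = 1); pairs whose earlier
    member is censored are not informative and are excluded. Concordant
    pairs score 1, risk ties 1/2.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=np.int64)
    if not (r.shape == t.shape == e.shape):
        raise ValueError("risk/time/event must be equal length")
    dt = t[:, None] - t[None, :]
    comparable = (dt < 0) & (e[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    dr = r[:, None] - r[None, :]
    concordant = comparable & (dr > 0)
    tied = comparable & (dr == 0)
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


@dataclass(frozen=True)
class EvaluationReport:
    confusion: ConfusionMatrix
    accuracy: float
    auc: float
    youden_threshold: float
    c_index: float
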