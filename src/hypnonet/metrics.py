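"""Confusion-matrix construction and sleep-staging metrics.

All reported numbers derive from one 5x5 integer confusion matrix whose
rows are the true stage and columns the predicted stage, in the fixed
order W, N1, N2, N3, REM.  Per-class precision, recall and F1 are reported
in percent; the overall summary is accuracy (ACC), macro-averaged F1 (MF1)
and Cohen's kappa, the chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),   p_e = sum_c rowsum_c * colsum_c / n^2.

Cross-validated results are *pooled*: fold predictions are concatenated
into one matrix, never averaged per fold.  Metrics are computed in full
precision; rounding (half-up, two decimals) happens only at reporting.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np

from .stages import N_STAGES, StageLabel

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion_matrix",
    "per_class_metrics", "overall_metrics", "pool_folds", "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, matching how results tables are
    conventionally printed (Python's round() would round half to even)."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """5x5 nonnegative integer counts; rows true, columns predicted."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"expected a {N_STAGES}x{N_STAGES} matrix")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    """Per-class (precision, recall, F1) in percent plus ACC/MF1/kappa."""

    per_class: dict  # stage name -> (pre %, re %, f1 %)
    acc: float
    mf1: float
    kappa: float

    def to_rows(self):
        for name, (pre, re, f1) in self.per_class.items():
            yield name, pre, re, f1


def confusion_matrix(true, pred) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #{true == i and pred == j}."""
    true = np.asarray(true, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if true.shape != pred.shape:
        raise ValueError(
            f"true and predicted label arrays differ in length "
            f"({true.size} vs {pred.size})"
        )
    if true.size and (
        true.min() < 0 or true.max() >= N_STAGES
        or pred.min() < 0 or pred.max() >= N_STAGES
    ):
        raise ValueError(f"labels must lie in 0..{N_STAGES - 1}")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts)


def _raw_per_class(cm: ConfusionMatrix):
    """Full-precision per-class (precision, recall, F1) as fractions."""
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    colsum = counts.sum(axis=0)
    rowsum = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pre = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        re = np.where(rowsum > 0, diag / np.where(rowsum > 0, rowsum, 1), 0.0)
        denom = pre + re
        f1 = np.where(denom > 0, 2 * pre * re / np.where(denom > 0, denom, 1), 0.0)
    return pre, re, f1


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class precision/recall/F1 in percent, rounded to two decimals.

    A class absent from the predictions gets precision 0 (and hence F1 0);
    a class absent from the truth gets recall 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pre, re, f1 = _raw_per_class(cm)
    return {
        stage.name: tuple(
            round_half_up(100 * v) for v in (pre[stage], re[stage], f1[stage])
        )
        for stage in StageLabel
    }


def overall_metrics(cm: ConfusionMatrix, *, rounded: bool = True):
    """(ACC %, MF1 %, kappa) from one pooled confusion matrix.

    ACC is trace/total, MF1 the unweighted mean of the five full-precision
    F1 values, and kappa the chance-corrected agreement.  With a degenerate
    single-class matrix p_e = 1 and kappa is undefined; it is reported as
    1 when the observed agreement is also perfect, otherwise this raises.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    total = counts.sum()
    acc = np.trace(counts) / total
    _, _, f1 = _raw_per_class(cm)
    mf1 = f1.mean()
    pe = float((counts.sum(axis=0) * counts.sum(axis=1)).sum() / total**2)
    if pe >= 1.0 - 1e-15:
        if acc >= 1.0 - 1e-15:
            kappa = 1.0
        else:
            raise ValueError("kappa undefined: expected agreement p_e = 1")
    else:
        kappa = (acc - pe) / (1 - pe)
    if rounded:
        return (
            round_half_up(100 * acc),
            round_half_up(100 * mf1),
            round_half_up(kappa),
        )
    return 100 * acc, 100 * mf1, kappa


def report(cm: ConfusionMatrix) -> MetricsReport:
    acc, mf1, kappa = overall_metrics(cm)
    return MetricsReport(
        per_class=per_class_metrics(cm), acc=acc, mf1=mf1, kappa=kappa
    )


def pool_folds(fold_predictions) -> ConfusionMatrix:
    """Concatenate (true, pred) pairs from every fold into one matrix.

    Pooling keeps every epoch's weight equal across folds; it is *not* an
    average of per-fold metrics.
    """
    fold_predictions = list(fold_predictions)
    if not fold_predictions:
        raise ValueError("need at least one fold")
    trues = np.concatenate([np.asarray(t, dtype=np.int64)
                            for t, _ in fold_predictions])
    preds = np.concatenate([np.asarray(p, dtype=np.int64)
                            for _, p in fold_predictions])
    return confusion_matrix(trues, preds)
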