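"""Confusion-count metrics and score-based curves for the LOO test set.

All count-based metrics are reported as percentages at full precision
(round for display); AUROC is computed by trapezoidal integration of the
ROC curve and AUPRC by step integration of the precision-recall curve.
Confidence intervals are 95% Wald normal approximations on each
proportion (clipped to [0, 100]); the AUROC interval uses the
Hanley-McNeil standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "compute_metrics", "roc_curve_points",
           "auroc_trapezoid", "auprc_step"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionCounts(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def _prop_ci(p_hat: float, m: int) -> tuple[float, float]:
    """95% Wald interval for a proportion (percent scale)."""
    if m == 0 or np.isnan(p_hat):
        return (float("nan"), float("nan"))
    se = np.sqrt(p_hat / 100 * (1 - p_hat / 100) / m) * 100
    return (float(np.clip(p_hat - 1.96 * se, 0, 100)),
            float(np.clip(p_hat + 1.96 * se, 0, 100)))


@dataclass
class MetricsReport:
    """The nine-metric panel, percentages for count metrics, [0, 1] for AUCs."""

    counts: ConfusionCounts
    recall: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    precision: float
    npv: float
    f1: float
    auroc: float = float("nan")
    auprc: float = float("nan")
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    METRIC_ORDER = (
        "recall", "specificity", "accuracy", "balanced_accuracy",
        "precision", "npv", "f1", "auroc", "auprc",
    )

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRIC_ORDER}

    def rounded(self) -> dict[str, float]:
        """Display form: integer percent for count metrics, 2 dp for AUCs."""
        out = {}
        for m in self.METRIC_ORDER:
            v = getattr(self, m)
            if m in ("auroc", "auprc"):
                out[m] = round(v, 2) if np.isfinite(v) else v
            else:
                out[m] = int(round(v)) if np.isfinite(v) else v
        return out


def roc_curve_points(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) at every distinct score threshold, ties grouped."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((1 - y).sum()), 1)
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return fpr, tpr


def auroc_trapezoid(y_true: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr = roc_curve_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def auprc_step(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by right-step integration
    (the average-precision estimator)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = int(y.sum())
    if n_pos == 0:
        return float("nan")
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    k = distinct + 1.0
    precision = tps / k
    recall = tps / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> MetricsReport:
    """The full metric panel from aggregated LOO confusion counts.

    Metrics with zero denominators are reported as NaN (undefined).
    ``scores``/``labels`` enable AUROC and AUPRC.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def frac(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    recall = frac(tp, tp + fn)
    specificity = frac(tn, tn + fp)
    accuracy = frac(tp + tn, counts.n)
    balanced = (recall + specificity) / 2
    precision = frac(tp, tp + fp)
    npv = frac(tn, tn + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)

    ci = {
        "recall": _prop_ci(recall, tp + fn),
        "specificity": _prop_ci(specificity, tn + fp),
        "accuracy": _prop_ci(accuracy, counts.n),
        "balanced_accuracy": _prop_ci(balanced, counts.n),
        "precision": _prop_ci(precision, tp + fp),
        "npv": _prop_ci(npv, tn + fn),
        "f1": _prop_ci(f1, counts.n),
    }

    auroc = auprc = float("nan")
    if scores is not None and labels is not None:
        labels = np.asarray(labels).astype(int)
        scores = np.asarray(scores, dtype=float)
        n_pos = int(labels.sum())
        n_neg = len(labels) - n_pos
        if n_pos and n_neg:
            auroc = auroc_trapezoid(labels, scores)
            auprc = auprc_step(labels, scores)
            se = _hanley_mcneil_se(auroc, n_pos, n_neg)
            ci["auroc"] = (
                float(np.clip(auroc - 1.96 * se, 0, 1)),
                float(np.clip(auroc + 1.96 * se, 0, 1)),
            )

    return MetricsReport(
        counts=counts,
        recall=recall,
        specificity=specificity,
        accuracy=accuracy,
        balanced_accuracy=balanced,
        precision=precision,
        npv=npv,
        f1=f1,
        auroc=auroc,
        auprc=auprc,
        ci=ci,
    )
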