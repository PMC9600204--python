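"""Classifier evaluation: confusion matrices, metrics with proportion
confidence intervals, ROC/AUC with fold averaging, and per-image timing.

Metrics are reported as percentages.  Each carries a 95 % half-width
``r = z * sqrt(m * (100 - m) / N)`` (z = 1.96), the normal-approximation
interval for a proportion expressed in percentage points.  ``N`` is the
pooled test count for accuracy and the per-class test count for the
class-conditional metrics (precision, recall, specificity, F1) and
their macro averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import LABELS
from .errors import ClockError, ParameterError

Z_95 = 1.96


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts for a designated positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same data with the other class designated positive."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp,
                               fp=self.fn, fn=self.fp)


def confusion(records, positive: str = "thalassaemia") -> ConfusionMatrix:
    """Count TP/TN/FP/FN from prediction records."""
    if not records:
        raise ParameterError("cannot build a confusion matrix from no records")
    if positive not in LABELS:
        raise ParameterError(f"unknown positive class {positive!r}")
    tp = tn = fp = fn = 0
    for r in records:
        actual_pos = r.true_label == positive
        predicted_pos = r.predicted_label == positive
        if actual_pos and predicted_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif predicted_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _pct(num: float, den: float) -> float:
    """Percentage with an explicit undefined marker for 0 denominators."""
    return math.nan if den == 0 else 100.0 * num / den


def _cm_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    recall = _pct(cm.tp, cm.tp + cm.fn)
    specificity = _pct(cm.tn, cm.tn + cm.fp)
    precision = _pct(cm.tp, cm.tp + cm.fp)
    f1 = _pct(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    return {
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
    }


def metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float] | float]:
    """Per-class and macro-averaged metrics, in percent.

    The positive-class matrix and its swap give the two per-class views;
    macro metrics are their unweighted means.  Accuracy is computed once
    on the pooled counts (it is invariant to the choice of positive
    class).  Undefined ratios (zero denominators) propagate as NaN.
    """
    pos = _cm_metrics(cm)
    neg = _cm_metrics(cm.swapped())
    macro = {
        key: (pos[key] + neg[key]) / 2.0 for key in pos
    }
    return {
        "accuracy": _pct(cm.tp + cm.tn, cm.total),
        "positive": pos,
        "negative": neg,
        "macro": macro,
    }


def confidence_interval(metric: float, n: int, z: float = Z_95) -> float:
    """95 % half-width of a percentage metric over N test samples.

    ``r = z * sqrt(metric * (100 - metric) / N)`` in percentage points;
    zero exactly at the 0 % and 100 % boundaries.
    """
    if n < 1:
        raise ParameterError(f"N must be >= 1, got {n}")
    if not (0.0 <= metric <= 100.0):
        raise ParameterError(f"metric must be a percentage, got {metric}")
    return z * math.sqrt(metric * (100.0 - metric) / n)


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage metric with its confidence half-width."""

    name: str
    value: float
    half_width: float
    n: int
    z: float = Z_95


def metric_report(
    cm: ConfusionMatrix, z: float = Z_95
) -> list[MetricEstimate]:
    """The headline table: accuracy plus macro metrics, each with its CI.

    N is the pooled test count for accuracy and the per-class test count
    (assumed balanced, as in the stratified protocol) for the macro
    metrics.
    """
    m = metrics(cm)
    n_total = cm.total
    n_class = (cm.tp + cm.fn + cm.tn + cm.fp) // 2
    rows = [
        MetricEstimate("accuracy", m["accuracy"],
                       confidence_interval(m["accuracy"], n_total, z),
                       n_total, z)
    ]
    for name in ("precision", "recall", "f1", "specificity"):
        value = m["macro"][name]
        rows.append(
            MetricEstimate(name, value,
                           confidence_interval(value, n_class, z),
                           n_class, z)
        )
    return rows


@dataclass
class ROCCurve:
    """An ROC curve with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(records) -> ROCCurve:
    """ROC by threshold sweep over the thalassaemia scores.

    Tied scores receive half credit (the curve passes through the tied
    block diagonally), so the trapezoidal AUC equals the Mann-Whitney
    concordant-pair fraction.
    """
    y = np.array([r.true_label == "thalassaemia" for r in records])
    scores = np.array([r.score for r in records], dtype=float)
    if y.all() or not y.any():
        raise ParameterError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), scores)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def average_roc(
    per_fold_records: list[list], grid_points: int = 101
) -> ROCCurve:
    """Vertical averaging of per-fold ROC curves on a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = []
    for records in per_fold_records:
        curve = roc_auc(records)
        tprs.append(np.interp(grid, curve.fpr, curve.tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    return ROCCurve(fpr=grid, tpr=mean_tpr,
                    auc=float(np.trapezoid(mean_tpr, grid)))


@dataclass(frozen=True)
class TimingRecord:
    """Wall-clock span of a batch and the per-image share."""

    t1: float
    t2: float
    n_images: int

    @property
    def delta_te(self) -> float:
        return self.t2 - self.t1

    @property
    def per_image(self) -> float:
        return self.delta_te / self.n_images


def elapsed_per_image(t1: float, t2: float, n_images: int = 1) -> float:
    """Elapsed seconds per image for a batch processed in [t1, t2]."""
    if n_images < 1:
        raise ParameterError(f"n_images must be >= 1, got {n_images}")
    if t2 < t1:
        raise ClockError(f"end time {t2} precedes start time {t1}")
    return (t2 - t1) / n_images


# ---------------------------------------------------------------------------
# report emission


def write_metric_csv(rows: list[MetricEstimate], path) -> None:
    """CSV report: metric, value, ci (half-width), N."""
    import pandas as pd

    pd.DataFrame(
        [
            {"metric": r.name, "value": r.value, "ci": r.half_width,
             "N": r.n, "z": r.z}
            for r in rows
        ]
    ).to_csv(path, index=False)


def write_summary_json(rows: list[MetricEstimate], path,
                       extra: dict | None = None) -> None:
    import json

    summary = {
        r.name: {"value": r.value, "ci": r.half_width, "N": r.n}
        for r in rows
    }
    if extra:
        summary.update(extra)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


def save_confusion_png(cm: ConfusionMatrix, path,
                       positive: str = "thalassaemia") -> None:
    """Render the 2x2 confusion matrix as an annotated heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    other = next(lb for lb in LABELS if lb != positive)
    counts = np.array([[cm.tp, cm.fn], [cm.fp, cm.tn]])
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], [positive, other])
    ax.set_yticks([0, 1], [positive, other])
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_roc_png(curves: dict[str, ROCCurve], path) -> None:
    """Plot one or more named ROC curves with their AUCs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr,
                label=f"{name} (AUC = {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
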