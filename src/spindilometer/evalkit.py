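"""Frame-level evaluation: confusion counts, derived metrics, ROC-AUC,
per-record count agreement (ICC), spindle counts and density.

The unit of evaluation is the 10-s frame: spindle present (1) or absent
(0).  Count agreement between two scorers (e.g. ground truth vs the
detector) is summarized by the two-way mixed, consistency-form intraclass
correlation, in both single-measures ICC(3,1) and average-measures
ICC(3,k) flavors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CountComparison",
    "confusion",
    "metrics",
    "roc_curve",
    "auc",
    "icc",
    "spindle_count",
    "density",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Derived binary-classification metrics; 0/0 ratios are reported as 0
    and listed in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }


@dataclass
class CountComparison:
    """Per-record spindle counts from two scorers and their agreement."""

    record_ids: list
    reference_counts: np.ndarray
    model_counts: np.ndarray
    icc_single: float
    icc_average: float
    reference_density_per_h: np.ndarray
    model_density_per_h: np.ndarray


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, [0, 1]).all():
        raise ValueError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion(actual, predicted) -> ConfusionCounts:
    """Confusion counts with spindle-present (1) as the positive class."""
    a = _check_binary(actual, "actual")
    p = _check_binary(predicted, "predicted")
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((a == 1) & (p == 1))),
        fp=int(np.sum((a == 0) & (p == 1))),
        tn=int(np.sum((a == 0) & (p == 0))),
        fn=int(np.sum((a == 1) & (p == 0))),
    )


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, F1 and MCC.

    accuracy = (TP+TN)/n, sensitivity (recall) = TP/(TP+FN), specificity =
    TN/(TN+FP), precision = TP/(TP+FP), F1 = 2PR/(P+R), MCC =
    (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if cc.n == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sens = ratio(cc.tp, cc.tp + cc.fn, "sensitivity")
    spec = ratio(cc.tn, cc.tn + cc.fp, "specificity")
    prec = ratio(cc.tp, cc.tp + cc.fp, "precision")
    f1 = ratio(2 * prec * sens, prec + sens, "f1")
    mcc_den = np.sqrt(
        float(cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    mcc = ratio(cc.tp * cc.tn - cc.fp * cc.fn, mcc_den, "mcc")
    return MetricsReport(
        accuracy=(cc.tp + cc.tn) / cc.n,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        mcc=mcc,
        undefined=undefined,
    )


def roc_curve(scores, actual) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve (fpr, tpr, thresholds) over all score thresholds."""
    a = _check_binary(actual, "actual")
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(a)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = skm.roc_curve(a, s)
    return fpr, tpr, thr


def auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve."""
    return float(skm.auc(fpr, tpr))


def icc(pairs: np.ndarray) -> tuple[float, float]:
    """Two-way mixed, consistency ICC of an (n_records, k_raters) table.

    From the two-way mean squares (rows = records, columns = raters):
    single measures ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE), average
    measures ICC(3,k) = (MSR - MSE) / MSR.
    """
    table = np.asarray(pairs, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need an (n_records, k>=2) table")
    n, k = table.shape
    if n < 3:
        raise ValueError("need at least 3 records")
    grand = table.mean()
    if np.allclose(table, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        raise ValueError("no between-record variance: ICC undefined")
    single = (msr - mse) / (msr + (k - 1) * mse)
    average = (msr - mse) / msr
    return float(single), float(average)


def spindle_count(frame_labels: np.ndarray) -> int:
    """Number of 10-s frames spindle-positive on at least one channel.

    ``frame_labels`` has shape (n_channels, n_frames); a frame positive on
    several channels simultaneously counts once (frame-union rule).
    """
    labels = _check_binary(frame_labels, "frame_labels")
    if labels.ndim == 1:
        labels = labels[None, :]
    return int(labels.any(axis=0).sum())


def density(count: int, recording_hours: float) -> float:
    """Spindle count per hour of recording."""
    if recording_hours <= 0:
        raise ValueError("recording duration must be positive")
    return count / recording_hours
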