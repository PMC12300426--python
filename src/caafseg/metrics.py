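"""Pixel-level evaluation metrics and the paired-t-test ablation statistic.

Metrics derive from the per-image confusion counts (TP, TN, FP, FN):
Dice = 2TP/(2TP+FN+FP), IoU = TP/(TP+FN+FP), sensitivity = TP/(TP+FN),
Miss Rate = FN/(TP+FN) and specificity = TN/(TN+FP). Degenerate
denominators are defined, not thrown: an empty target means there are no
positives to find (sensitivity 1, Miss Rate 0), and when prediction and
target are both empty the overlap metrics are vacuously perfect.

Per-case metrics are aggregated as mean ± standard deviation across
cases (not pooled-pixel), and a fixed-column CSV report is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nn import Tensor

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "PairedTestResult",
    "confusion",
    "compute_metrics",
    "paired_t_test",
    "report_frame",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["case_id", "dice", "iou", "sensitivity", "miss_rate",
                  "specificity", "w1", "w2"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    dice: float
    iou: float
    sensitivity: float
    miss_rate: float
    specificity: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    mean_difference: float
    n: int
    zero_variance: bool = False


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        x = x.data
    return np.asarray(x)


def confusion(pred, target, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize the prediction at ``threshold`` and tally pixel counts."""
    p = _as_array(pred)
    t = _as_array(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    if not np.all((t == 0) | (t == 1)):
        raise ValueError("target mask must be binary")
    pb = p >= threshold
    tb = t > 0
    tp = int(np.count_nonzero(pb & tb))
    tn = int(np.count_nonzero(~pb & ~tb))
    fp = int(np.count_nonzero(pb & ~tb))
    fn = int(np.count_nonzero(~pb & tb))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate the five metrics from confusion counts.

    Degenerate branches: both masks empty → Dice = IoU = 1 (vacuous
    success); empty target → sensitivity = 1, Miss Rate = 0; no true
    negatives possible (TN + FP = 0) → specificity = 1.
    """
    overlap_den = 2 * c.tp + c.fn + c.fp
    dice = 2 * c.tp / overlap_den if overlap_den else 1.0
    iou_den = c.tp + c.fn + c.fp
    iou = c.tp / iou_den if iou_den else 1.0
    pos = c.tp + c.fn
    sensitivity = c.tp / pos if pos else 1.0
    miss_rate = c.fn / pos if pos else 0.0
    neg = c.tn + c.fp
    specificity = c.tn / neg if neg else 1.0
    return MetricReport(dice=dice, iou=iou, sensitivity=sensitivity,
                        miss_rate=miss_rate, specificity=specificity)


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> PairedTestResult:
    """Two-tailed paired t-test on d = a − b.

    t = mean(d) / (sd(d)/√n) with sd the sample standard deviation
    (n − 1 denominator); p from Student's t with n − 1 degrees of
    freedom. Zero-variance differences are flagged: p is 0 when the mean
    difference is nonzero and 1 when it is zero.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired scores must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    # constant differences up to float rounding count as zero variance
    if sd <= 1e-12 * max(abs(mean), 1.0):
        if mean == 0.0:
            return PairedTestResult(0.0, 1.0, 0.0, n, zero_variance=True)
        t = float(np.inf) if mean > 0 else float(-np.inf)
        return PairedTestResult(t, 0.0, mean, n, zero_variance=True)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(float(t), p, mean, n)


def report_frame(case_ids: Sequence, reports: Sequence[MetricReport],
                 weights: Sequence | None = None) -> pd.DataFrame:
    """One row per case in the fixed column order, plus a mean summary row."""
    if weights is None:
        weights = [(np.nan, np.nan)] * len(reports)
    rows = []
    for cid, rep, (w1, w2) in zip(case_ids, reports, weights):
        rows.append({"case_id": cid, **rep.as_dict(), "w1": float(w1), "w2": float(w2)})
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    summary = frame[REPORT_COLUMNS[1:]].mean()
    summary["case_id"] = "mean"
    frame = pd.concat([frame, summary.to_frame().T[REPORT_COLUMNS]], ignore_index=True)
    return frame
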