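"""Cohort screening statistics: confusion counts, rates, ROC.

Positive class = anomaly/cancer throughout, and calls use "score >=
threshold", matching the single-patient classifier.  Rates are kept at
full precision internally; printed values use truncation to two decimals
(``truncate-2``), the display convention that reproduces percentages
such as 136/198 -> 68.68 and 8/70 -> 11.42.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ScreeningReport",
    "ROCCurve",
    "confusion",
    "screening_statistics",
    "roc_curve",
    "truncate2",
    "evaluate_cohort",
]


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals; NaN passes through."""
    if math.isnan(x):
        return x
    return math.floor(x * 100.0) / 100.0


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ScreeningReport:
    """Sensitivity/specificity/PPV/NPV in percent, full precision.

    Statistics whose denominator is zero are NaN and listed in
    ``undefined``.  ``display()`` applies truncate-2 rounding.
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: list[str] = field(default_factory=list)

    def display(self) -> dict[str, float]:
        return {
            "sensitivity": truncate2(self.sensitivity),
            "specificity": truncate2(self.specificity),
            "ppv": truncate2(self.ppv),
            "npv": truncate2(self.npv),
        }

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, "n": c.total,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "undefined": list(self.undefined),
        }


@dataclass
class ROCCurve:
    """ROC points from sweeping the score threshold; trapezoidal AUC."""

    thresholds: np.ndarray  # descending; +inf first
    points: np.ndarray      # (n, 2) array of (fpr, tpr), from (0,0) to (1,1)
    auc: float


def _as_binary(v: Sequence, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.dtype.kind in "SUO":  # allow healthy/anomaly string vectors
        mapping = {"healthy": 0, "anomaly": 1, "0": 0, "1": 1}
        try:
            arr = np.array([mapping[str(x)] for x in arr])
        except KeyError as exc:
            raise ValueError(f"non-binary entry in {name}: {exc.args[0]!r}") from None
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"non-binary entries in {name}")
    return arr.astype(int)


def confusion(labels: Sequence, predictions: Sequence) -> ConfusionCounts:
    """2x2 tally of predictions against truth (positive = anomaly = 1)."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def screening_statistics(c: ConfusionCounts) -> ScreeningReport:
    """Standard screening rates in percent from a 2x2 table."""
    report = ScreeningReport(
        counts=c,
        sensitivity=_rate(c.tp, c.tp + c.fn),
        specificity=_rate(c.tn, c.tn + c.fp),
        ppv=_rate(c.tp, c.tp + c.fp),
        npv=_rate(c.tn, c.tn + c.fn),
    )
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        if math.isnan(getattr(report, name)):
            report.undefined.append(name)
    return report


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """ROC over thermal-score thresholds (call anomaly when score >= t).

    Thresholds sweep the sorted unique scores from high to low, with a
    leading +inf so the curve starts at (0, 0); it necessarily ends at
    (1, 1) when every case is called positive.  AUC is trapezoidal.
    """
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    pts = np.empty((len(thresholds), 2))
    for i, thr in enumerate(thresholds):
        calls = s >= thr
        pts[i, 0] = (calls & (y == 0)).sum() / n_neg  # fpr
        pts[i, 1] = (calls & (y == 1)).sum() / n_pos  # tpr
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCCurve(thresholds=thresholds, points=pts, auc=auc)


def evaluate_cohort(
    cohort: pd.DataFrame, threshold: float = 2.5
) -> tuple[ScreeningReport, ROCCurve]:
    """Screen a cohort table with columns ``score`` and ``truth_label``.

    ``truth_label`` may be 0/1 or healthy/anomaly strings.  Returns the
    2x2 report at the given threshold plus the full ROC sweep.
    """
    for col in ("score", "truth_label"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing column {col!r}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    scores = cohort["score"].to_numpy(dtype=float)
    labels = _as_binary(cohort["truth_label"].to_numpy(), "truth_label")
    predictions = (scores >= threshold).astype(int)
    report = screening_statistics(confusion(labels, predictions))
    roc = roc_curve(scores, labels)
    return report, roc
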