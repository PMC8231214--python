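"""Classification metrics: precision, recall, F1, confusion matrices,
macro vs support-weighted aggregation, and bootstrap confidence intervals.

Conventions: degenerate 0/0 ratios (a class never predicted and never
present) are reported as 0. "Overall" scores on balanced sets are macro
averages; support-weighted averages are for unbalanced full-trace
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import BehaviourLabel

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "prf1",
    "aggregate",
    "bootstrap_ci",
]

_N_CLASSES = len(BehaviourLabel)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = _N_CLASSES
) -> tuple[np.ndarray, np.ndarray]:
    """Raw counts (entry [i, j]: true class i predicted as j) and the
    row-normalised matrix (rows with zero support stay all-zero)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label sequences differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalised = np.where(row_sums > 0, counts / row_sums, 0.0)
    return counts, normalised


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from true/false positive and false negative
    counts; 0/0 ratios return 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics for one evaluation."""

    confusion: np.ndarray
    confusion_normalised: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray

    @classmethod
    def from_labels(cls, y_true, y_pred, n_classes: int = _N_CLASSES) -> "MetricsReport":
        counts, normalised = confusion_matrix(y_true, y_pred, n_classes)
        tp = np.diag(counts).astype(np.int64)
        fp = counts.sum(axis=0) - tp
        fn = counts.sum(axis=1) - tp
        per_class = np.array([prf1(int(t), int(p), int(n)) for t, p, n in zip(tp, fp, fn)])
        return cls(
            confusion=counts,
            confusion_normalised=normalised,
            tp=tp,
            fp=fp,
            fn=fn,
            precision=per_class[:, 0],
            recall=per_class[:, 1],
            f1=per_class[:, 2],
            support=counts.sum(axis=1),
        )

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            },
            index=[c.name for c in BehaviourLabel][: len(self.f1)],
        )

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [frame.round(3).to_string()]
        lines.append(
            f"macro    P={self.macro_precision:.3f} "
            f"R={self.macro_recall:.3f} F1={self.macro_f1:.3f}"
        )
        w = aggregate(self, "weighted")
        lines.append(f"weighted P={w['precision']:.3f} R={w['recall']:.3f} F1={w['f1']:.3f}")
        return "\n".join(lines)


def aggregate(report: MetricsReport, mode: str) -> dict[str, float]:
    """Aggregate per-class metrics: ``macro`` (unweighted class mean) or
    ``weighted`` (support-weighted mean)."""
    if mode == "macro":
        weights = np.ones_like(report.f1) / len(report.f1)
    elif mode == "weighted":
        total = report.support.sum()
        if total == 0:
            weights = np.zeros_like(report.f1)
        else:
            weights = report.support / total
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return {
        "precision": float(weights @ report.precision),
        "recall": float(weights @ report.recall),
        "f1": float(weights @ report.f1),
    }


def bootstrap_ci(
    scores,
    level: float = 0.95,
    resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``scores``."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("bootstrap needs at least 2 scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(resamples, scores.size))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)
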