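"""Confusion matrices and precision/recall/F1/accuracy reports.

Reports follow the standard class-based + aggregate layout: one row per
class, then macro (unweighted class mean) and support-weighted averages,
then overall accuracy.  All arithmetic is double precision; values are
rounded to four decimals only when rendered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix", "metrics_report",
           "render_report", "parse_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = number of items with true class i predicted as class j."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        k = len(self.class_names)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    supports: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "classes": {
                name: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.supports[i]),
                }
                for i, name in enumerate(self.class_names)
            },
            "macro_avg": {"precision": self.macro_precision, "recall": self.macro_recall,
                          "f1": self.macro_f1},
            "weighted_avg": {"precision": self.weighted_precision, "recall": self.weighted_recall,
                             "f1": self.weighted_f1},
            "accuracy": self.accuracy,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def confusion_matrix(y_true, y_pred, class_names) -> ConfusionMatrix:
    class_names = tuple(class_names)
    index = {name: i for i, name in enumerate(class_names)}
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        ti = index.get(t, t if isinstance(t, (int, np.integer)) and 0 <= t < k else None)
        pi = index.get(p, p if isinstance(p, (int, np.integer)) and 0 <= p < k else None)
        if ti is None or pi is None:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[ti, pi] += 1
    return ConfusionMatrix(counts, class_names)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and aggregate precision/recall/F1 plus accuracy.

    A never-predicted class gets precision 0 (with a warning); an absent
    class gets recall 0 likewise.  Weighted averages weight by true-class
    support, so weighted recall equals accuracy for single-label data.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    pred_totals = counts.sum(axis=0)
    supports = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(supports > 0, tp / supports, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if np.any(pred_totals == 0):
        warnings.warn(
            f"classes never predicted: "
            f"{[cm.class_names[i] for i in np.flatnonzero(pred_totals == 0)]}; "
            "their precision is reported as 0",
            stacklevel=2,
        )
    w = supports / total
    return MetricsReport(
        class_names=cm.class_names,
        precision=precision,
        recall=recall,
        f1=f1,
        supports=supports.astype(np.int64),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(w @ precision),
        weighted_recall=float(w @ recall),
        weighted_f1=float(w @ f1),
        accuracy=float(tp.sum() / total),
    )


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def render_report(report: MetricsReport) -> str:
    """Fixed-order text table: class rows, Macro Avg., Weighted Avg., Accuracy."""
    name_w = max(15, max(len(n) for n in report.class_names) + 2)
    lines = [f"{'Classes':<{name_w}}{'Precision':>10}{'Recall':>10}{'F1-Score':>10}"]
    for i, name in enumerate(report.class_names):
        lines.append(
            f"{name:<{name_w}}{_fmt(report.precision[i]):>10}"
            f"{_fmt(report.recall[i]):>10}{_fmt(report.f1[i]):>10}"
        )
    lines.append(
        f"{'Macro Avg.':<{name_w}}{_fmt(report.macro_precision):>10}"
        f"{_fmt(report.macro_recall):>10}{_fmt(report.macro_f1):>10}"
    )
    lines.append(
        f"{'Weighted Avg.':<{name_w}}{_fmt(report.weighted_precision):>10}"
        f"{_fmt(report.weighted_recall):>10}{_fmt(report.weighted_f1):>10}"
    )
    lines.append(f"{'Accuracy':<{name_w}}{_fmt(report.accuracy):>10}")
    return "\n".join(lines)


def parse_report(text: str) -> dict:
    """Parse a rendered table back to a nested dict of floats (4-decimal)."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    out: dict = {"classes": {}}
    for ln in lines[1:]:
        parts = ln.rsplit(None, 3)
        name = parts[0].strip()
        if name == "Accuracy":
            out["accuracy"] = float(parts[1])
        elif name in ("Macro Avg.", "Weighted Avg."):
            key = "macro_avg" if name.startswith("Macro") else "weighted_avg"
            out[key] = {"precision": float(parts[1]), "recall": float(parts[2]),
                        "f1": float(parts[3])}
        else:
            out["classes"][name] = {"precision": float(parts[1]), "recall": float(parts[2]),
                                    "f1": float(parts[3])}
    return out
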