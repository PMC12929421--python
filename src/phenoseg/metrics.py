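"""Confusion-matrix evaluation for binary (plant/background) segmentation.

Per class c treated as positive:

    IoU = TP / (TP + FP + FN)            Acc = (TP + TN) / total
    P   = TP / (TP + FP)                 R   = TP / (TP + FN)
    F1  = 2PR / (P + R)  =  Dice = 2TP / (2TP + FP + FN)

Zero-denominator cases yield NaN sentinels which are excluded from macro
averages rather than silently mapped to 0 or 1. Values are fractions in
[0, 1]; ``MetricReport.as_percent_table`` renders the conventional
percentage layout (class rows plus an unweighted "Average" row). The
per-class accuracy column of that layout equals per-class recall and is
labelled as such; global accuracy is reported separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "MetricReport",
    "confusion",
    "compute_metrics",
    "dice",
    "macro_iou",
]

CLASS_NAMES = ("background", "plant")


@dataclass
class ConfusionCounts:
    """Per-class TP/TN/FP/FN pixel counts (each class in turn as positive)."""

    per_class: dict[str, dict[str, int]]
    total: int

    def __post_init__(self) -> None:
        for name, c in self.per_class.items():
            s = c["tp"] + c["tn"] + c["fp"] + c["fn"]
            if s != self.total:
                raise ValueError(
                    f"counts for class {name!r} sum to {s}, expected {self.total}")


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts for {0, 1} class maps of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(truth)) <= {0, 1}):
        raise ValueError("class maps must contain only values {0, 1}")
    joint = np.bincount(2 * truth.astype(np.int64).ravel() + pred.ravel(),
                        minlength=4)
    n00, n01, n10, n11 = (int(v) for v in joint)  # truth,pred pairs
    total = int(pred.size)
    per_class = {
        "background": {"tp": n00, "fp": n10, "fn": n01, "tn": n11},
        "plant": {"tp": n11, "fp": n01, "fn": n10, "tn": n00},
    }
    return ConfusionCounts(per_class=per_class, total=total)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


@dataclass
class ClassMetrics:
    iou: float
    accuracy: float          # global accuracy (same for both classes)
    f1: float
    precision: float
    recall: float

    def as_dict(self) -> dict[str, float]:
        return {"IoU": self.iou, "Accuracy": self.accuracy, "F1": self.f1,
                "Precision": self.precision, "Recall": self.recall}


@dataclass
class MetricReport:
    per_class: dict[str, ClassMetrics]
    macro: ClassMetrics
    global_accuracy: float

    def as_percent_table(self, decimals: int = 2) -> list[dict]:
        """Rows {class, IoU, Accuracy, F1, Precision, Recall} in percent;
        the per-class Accuracy column carries recall-as-accuracy for layout
        parity with per-class tables, the Average row the macro means."""
        rows = []
        for name, m in self.per_class.items():
            rows.append({"class": name,
                         "IoU": round(100 * m.iou, decimals),
                         "Accuracy": round(100 * m.recall, decimals),
                         "F1": round(100 * m.f1, decimals),
                         "Precision": round(100 * m.precision, decimals),
                         "Recall": round(100 * m.recall, decimals)})
        avg = {"class": "Average",
               "IoU": round(100 * self.macro.iou, decimals),
               "Accuracy": round(100 * self.macro.recall, decimals),
               "F1": round(100 * self.macro.f1, decimals),
               "Precision": round(100 * self.macro.precision, decimals),
               "Recall": round(100 * self.macro.recall, decimals)}
        rows.append(avg)
        return rows

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_class": {k: v.as_dict() for k, v in self.per_class.items()},
            "macro": self.macro.as_dict(),
            "global_accuracy": self.global_accuracy,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_csv(self, path: str | Path) -> None:
        rows = self.as_percent_table()
        header = ["class", "IoU", "Accuracy", "F1", "Precision", "Recall"]
        lines = [",".join(header)]
        lines += [",".join(str(r[h]) for h in header) for r in rows]
        Path(path).write_text("\n".join(lines) + "\n")


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Evaluate the metric formulas per class plus unweighted macro means."""
    per_class: dict[str, ClassMetrics] = {}
    global_acc = math.nan
    for name, c in counts.per_class.items():
        tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]
        iou = _safe_div(tp, tp + fp + fn)
        acc = _safe_div(tp + tn, tp + tn + fp + fn)
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        f1 = (2 * prec * rec / (prec + rec)
              if (prec + rec) > 0 and not (math.isnan(prec) or math.isnan(rec))
              else math.nan)
        per_class[name] = ClassMetrics(iou=iou, accuracy=acc, f1=f1,
                                       precision=prec, recall=rec)
        global_acc = acc

    def nanmean(vals: list[float]) -> float:
        ok = [v for v in vals if not math.isnan(v)]
        return sum(ok) / len(ok) if ok else math.nan

    macro = ClassMetrics(
        iou=nanmean([m.iou for m in per_class.values()]),
        accuracy=global_acc,
        f1=nanmean([m.f1 for m in per_class.values()]),
        precision=nanmean([m.precision for m in per_class.values()]),
        recall=nanmean([m.recall for m in per_class.values()]),
    )
    return MetricReport(per_class=per_class, macro=macro,
                        global_accuracy=global_acc)


def dice(counts: ConfusionCounts) -> dict[str, float]:
    """Per-class Dice = 2TP/(2TP+FP+FN); equals F1 on binary masks."""
    out = {}
    for name, c in counts.per_class.items():
        out[name] = _safe_div(2 * c["tp"], 2 * c["tp"] + c["fp"] + c["fn"])
    return out


def macro_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Convenience: unweighted mean IoU over both classes."""
    return compute_metrics(confusion(pred, truth)).macro.iou
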