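"""Per-class pixel metrics for grain/impurity segmentation.

Definitions (per class, from pooled pixel counts):

    P      = TP / (TP + FP)                 precision
    R      = TP / (TP + FN)                 recall
    F1     = 2 P R / (P + R)                comprehensive evaluation index
    F_IOU  = TP / (TP + FN + FP)            intersection over union
    F_MIOU = mean of the per-class F_IOU    (grain and impurity only;
                                             background is excluded)

``metrics_from_pr`` recomputes F1 and F_IOU from printed precision/recall
alone via the identity F_IOU = P*R / (P + R - P*R), which lets published
tables be verified without the underlying masks.

A metric whose denominator is zero is *undefined*: it is returned as the
module constant ``UNDEFINED`` (NaN), announced with a warning, and excluded
from averages - never silently reported as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNDEFINED",
    "ConfusionTable",
    "ClassMetrics",
    "SummaryMetrics",
    "confusion",
    "precision",
    "recall",
    "f1",
    "iou",
    "metrics_from_pr",
    "miou",
    "class_metrics",
    "evaluate_set",
]

UNDEFINED = float("nan")

CLASS_NAMES = {1: "grain", 2: "impurity"}
EVAL_CLASSES = (1, 2)  # background (0) is not scored


def _undefined(what: str) -> float:
    warnings.warn(f"{what} is undefined (zero denominator)", stacklevel=3)
    return UNDEFINED


@dataclass(frozen=True)
class ConfusionTable:
    """Pixel-level TP/FP/FN for one class (TN implicit)."""

    class_id: int
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        if self.class_id != other.class_id:
            raise ValueError("cannot pool confusion tables of different classes")
        return ConfusionTable(
            self.class_id, self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    iou: float


@dataclass(frozen=True)
class SummaryMetrics:
    per_class: dict[int, ClassMetrics]
    f_miou: float
    i_v_ms: float = UNDEFINED

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, cm in self.per_class.items():
            rows.append(
                {
                    "class": CLASS_NAMES.get(cid, str(cid)),
                    "P": cm.precision,
                    "R": cm.recall,
                    "F1": cm.f1,
                    "F_IOU": cm.iou,
                    "F_MIOU": self.f_miou,
                    "I_v_ms": self.i_v_ms,
                }
            )
        return pd.DataFrame(rows)

    def format_table(self) -> str:
        df = self.to_frame().copy()
        for col in ("P", "R", "F1"):
            df[col] = (df[col] * 100).map("{:.2f}".format)
        for col in ("F_IOU", "F_MIOU"):
            df[col] = df[col].map("{:.4f}".format)
        return df.to_string(index=False)


def confusion(pred: np.ndarray, truth: np.ndarray, class_id: int) -> ConfusionTable:
    """Pixel confusion counts of ``class_id`` between two label masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionTable(class_id, tp, fp, fn)


def precision(t: ConfusionTable) -> float:
    denom = t.tp + t.fp
    return t.tp / denom if denom else _undefined("precision")


def recall(t: ConfusionTable) -> float:
    denom = t.tp + t.fn
    return t.tp / denom if denom else _undefined("recall")


def f1(p: float, r: float) -> float:
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        return _undefined("F1")
    return 2.0 * p * r / (p + r)


def iou(t: ConfusionTable) -> float:
    denom = t.tp + t.fn + t.fp
    return t.tp / denom if denom else _undefined("IOU")


def metrics_from_pr(p: float, r: float) -> tuple[float, float]:
    """(F1, F_IOU) from precision and recall alone.

    F_IOU follows from TP/(TP+FN+FP) by dividing through by TP:
    F_IOU = 1 / (1/P + 1/R - 1) = P*R / (P + R - P*R).
    """
    if not (0 < p <= 1 and 0 < r <= 1):
        return _undefined("F1"), UNDEFINED
    return 2.0 * p * r / (p + r), p * r / (p + r - p * r)


def miou(ious) -> float:
    """Arithmetic mean of per-class IOUs; undefined entries are excluded."""
    ious = list(ious)
    if not ious:
        raise ValueError("miou of an empty list")
    defined = [x for x in ious if not math.isnan(x)]
    if len(defined) < len(ious):
        warnings.warn(
            f"excluding {len(ious) - len(defined)} undefined IOU(s) from the mean",
            stacklevel=2,
        )
    if not defined:
        return UNDEFINED
    return float(np.mean(defined))


def class_metrics(t: ConfusionTable) -> ClassMetrics:
    p, r = precision(t), recall(t)
    return ClassMetrics(p, r, f1(p, r), iou(t))


def evaluate_set(
    predictions, truths, i_v_ms: float = UNDEFINED
) -> SummaryMetrics:
    """Pooled (micro) evaluation over an image set.

    Confusion counts are summed over all images per class before the
    metric formulas are applied.
    """
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truths)} ground truths"
        )
    if not predictions:
        raise ValueError("empty evaluation set")
    per_class = {}
    ious = []
    for cid in EVAL_CLASSES:
        pooled = ConfusionTable(cid, 0, 0, 0)
        for pred, truth in zip(predictions, truths):
            pooled = pooled + confusion(pred, truth, cid)
        cm = class_metrics(pooled)
        per_class[cid] = cm
        ious.append(cm.iou)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_miou = miou(ious)
    return SummaryMetrics(per_class=per_class, f_miou=f_miou, i_v_ms=i_v_ms)
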