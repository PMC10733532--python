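"""Per-image confusion counting, overlap metrics and summary tables.

Metrics follow the usual pixel-wise definitions on binary masks:

    Dice = 2 TP / (FP + FN + 2 TP)      IoU = TP / (FP + FN + TP)
    Accuracy = (TP + TN) / all          Precision = TP / (TP + FP)

They are computed per image and then averaged (mean +/- sample standard
deviation) across the test set, matching the protocol behind the published
benchmark tables.  Conventions for degenerate cases: Dice and IoU are 1.0
when prediction and truth are both empty; precision is undefined (None)
when the prediction contains no positives, and such records are excluded
from its summary.  Both conventions are logged when they fire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_NAMES = ("dice", "iou", "accuracy", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts of one predicted mask against ground truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricRecord:
    """Evaluation metrics of one image; precision may be None (undefined)."""

    image_id: str
    dice: float
    iou: float
    accuracy: float
    precision: float | None


def _check_binary(a, name):
    a = np.asarray(a)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} mask must be strictly binary, found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    """Count TP/TN/FP/FN of a binary prediction against a binary truth."""
    pred = _check_binary(pred_mask, "prediction")
    gt = _check_binary(gt_mask, "ground truth")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}")
    return ConfusionCounts(tp=int(np.sum(pred & gt)), tn=int(np.sum(~pred & ~gt)),
                           fp=int(np.sum(pred & ~gt)), fn=int(np.sum(~pred & gt)))


def dice(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        logger.info("dice: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2 * c.tp / (c.fp + c.fn + 2 * c.tp)


def iou(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        logger.info("iou: both masks empty; returning 1.0 by convention")
        return 1.0
    return c.tp / (c.fp + c.fn + c.tp)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined for empty images")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float | None:
    if c.tp + c.fp == 0:
        logger.info("precision: no predicted positives; reporting as missing")
        return None
    return c.tp / (c.tp + c.fp)


def binarize(probs, threshold=0.5):
    """Threshold a probability map into a binary mask."""
    return (np.asarray(probs) > threshold).astype(np.uint8)


def metric_record(pred_mask, gt_mask, image_id="") -> MetricRecord:
    c = confusion_counts(pred_mask, gt_mask)
    return MetricRecord(image_id=image_id, dice=dice(c), iou=iou(c),
                        accuracy=accuracy(c), precision=precision(c))


def summarize(records) -> pd.DataFrame:
    """Mean and sample standard deviation of each metric across images.

    Undefined precision values are dropped from the precision row; a single
    record yields std 0.
    """
    records = list(records)
    if not records:
        raise ValueError("summarize requires at least one record")
    rows = []
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in records]
        vals = [v for v in vals if v is not None]
        if not vals:
            rows.append({"metric": name, "mean": np.nan, "std": np.nan, "n": 0})
            continue
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"metric": name, "mean": mean, "std": std, "n": len(vals)})
    return pd.DataFrame(rows)


def improvement(a: float, b: float) -> float:
    """Relative improvement of a over b, in percent: 100 * (a - b) / b."""
    if b == 0:
        raise ValueError("improvement undefined over a zero baseline")
    return 100.0 * (a - b) / b


def model_comparison(model_records: dict, reference: str | None = None) -> pd.DataFrame:
    """Summary table over several models, one row per (model, metric).

    With ``reference`` set, adds improvement rows giving the percentage gain
    of the reference model's mean over every other model, per metric.
    """
    rows = []
    means = {}
    for model, records in model_records.items():
        summary = summarize(records)
        means[model] = dict(zip(summary["metric"], summary["mean"]))
        for _, r in summary.iterrows():
            rows.append({"model": model, "metric": r["metric"],
                         "mean": r["mean"], "std": r["std"]})
    if reference is not None:
        for model in model_records:
            if model == reference:
                continue
            for name in METRIC_NAMES:
                a, b = means[reference][name], means[model][name]
                rows.append({"model": f"{reference} over {model} (%)",
                             "metric": name,
                             "mean": improvement(a, b), "std": np.nan})
    return pd.DataFrame(rows)
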