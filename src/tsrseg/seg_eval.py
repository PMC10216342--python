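"""Pixel-wise segmentation evaluation: confusion matrix and metrics.

Ground-truth pixels labeled artifact are excluded. The confusion matrix is
5x5 with rows = ground truth and columns = prediction; macro averages
weight all classes equally regardless of pixel counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import ARTIFACT, CLASS_NAMES, N_PREDICTED


@dataclass
class ConfusionMatrix:
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_PREDICTED, N_PREDICTED),
                                         dtype=np.int64))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_PREDICTED, N_PREDICTED):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized_percent(self) -> np.ndarray:
        """Rows normalized to 100% (rows with no pixels stay zero)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, 100.0 * self.counts / sums, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        names = CLASS_NAMES[:N_PREDICTED]
        return pd.DataFrame(self.counts, index=names, columns=names)


def accumulate_confusion(gt: np.ndarray, pred: np.ndarray,
                         existing: ConfusionMatrix | None = None
                         ) -> ConfusionMatrix:
    """Add the pixel-wise (gt, pred) pairs of one image to a matrix."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs "
                         f"pred {pred.shape}")
    if gt.size and (gt.min() < 0 or gt.max() > ARTIFACT):
        raise ValueError("gt values must be in 0..5")
    if pred.size and (pred.min() < 0 or pred.max() >= N_PREDICTED):
        raise ValueError("pred values must be in 0..4")
    keep = gt != ARTIFACT
    idx = gt[keep] * N_PREDICTED + pred[keep]
    add = np.bincount(idx, minlength=N_PREDICTED * N_PREDICTED)
    cm = existing if existing is not None else ConfusionMatrix()
    return ConfusionMatrix(cm.counts +
                           add.reshape(N_PREDICTED, N_PREDICTED))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Per-class recall/precision/IoU/F1 and overall (macro) averages.

    Classes with neither ground-truth nor predicted pixels are excluded
    from the macro means; a class that appears but has no true positives
    scores 0 on every metric.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    gt_tot = counts.sum(axis=1)
    pr_tot = counts.sum(axis=0)
    per_class = {}
    active = []
    for c in range(N_PREDICTED):
        if gt_tot[c] == 0 and pr_tot[c] == 0:
            continue
        active.append(c)
        fn = gt_tot[c] - tp[c]
        fp = pr_tot[c] - tp[c]
        recall = _safe_div(tp[c], tp[c] + fn)
        precision = _safe_div(tp[c], tp[c] + fp)
        iou = _safe_div(tp[c], tp[c] + fp + fn)
        f1 = _safe_div(2 * precision * recall, precision + recall)
        per_class[CLASS_NAMES[c]] = {
            "recall": recall, "precision": precision,
            "iou": iou, "f1": f1,
        }
    overall = {
        "accuracy": tp.sum() / cm.total,
        "macro_recall": float(np.mean([per_class[CLASS_NAMES[c]]["recall"]
                                       for c in active])),
        "macro_precision": float(np.mean(
            [per_class[CLASS_NAMES[c]]["precision"] for c in active])),
        "macro_iou": float(np.mean([per_class[CLASS_NAMES[c]]["iou"]
                                    for c in active])),
        "macro_f1": float(np.mean([per_class[CLASS_NAMES[c]]["f1"]
                                   for c in active])),
    }
    return {"per_class": per_class, "overall": overall}


def metrics_table(metric_dicts: list[dict]) -> pd.DataFrame:
    """Aggregate overall metrics from several runs as mean +/- SD."""
    rows = [m["overall"] for m in metric_dicts]
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)
                         if len(df) > 1 else 0.0})
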