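"""Evaluation metrics for segmentation masks and binary classification.

Segmentation: Jaccard similarity index (JSI, |A n B| / |A u B|), Dice
coefficient (DC, 2|A n B| / (|A| + |B|)), plus pixel-level accuracy /
precision / recall / specificity.  Classification: the same rate metrics
from an image-level confusion matrix, F1, and ROC AUC.  HD95 (95th
percentile of symmetric boundary distances) is available as an optional
contour metric.

Degenerate 0/0 rates are reported as absent (``None``) with a warning
rather than coerced to 0 or 1, so that averages over experiments are not
biased by undefined entries.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "classification_metrics",
    "segmentation_metrics",
    "auc",
    "hd95",
    "write_report",
]


@dataclasses.dataclass(frozen=True)
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


@dataclasses.dataclass
class MetricRecord:
    """Bundle of rate metrics, each in [0, 1] or ``None`` when undefined."""

    jsi: float | None = None
    dc: float | None = None
    acc: float | None = None
    pre: float | None = None
    rec: float | None = None
    spe: float | None = None
    f1: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion(pred_labels, true_labels, positive_class) -> ConfusionCounts:
    """Image-level confusion counts for a binary problem."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("pred and true label lists differ in length")
    pp = pred == positive_class
    tp_ = true == positive_class
    return ConfusionCounts(tp=int(np.sum(pp & tp_)), tn=int(np.sum(~pp & ~tp_)),
                           fp=int(np.sum(pp & ~tp_)), fn=int(np.sum(~pp & tp_)))


def _rate(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (0/0); reported absent", stacklevel=3)
        return None
    return num / den


def classification_metrics(counts: ConfusionCounts) -> MetricRecord:
    """ACC, PRE, REC (sensitivity), SPE, F1 from confusion counts."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    pre = _rate(tp, tp + fp, "PRE")
    rec = _rate(tp, tp + fn, "REC")
    spe = _rate(tn, tn + fp, "SPE")
    f1 = None
    if pre is not None and rec is not None:
        if pre + rec == 0:
            warnings.warn("F1 undefined (0/0); reported absent", stacklevel=2)
        else:
            f1 = 2 * pre * rec / (pre + rec)
    return MetricRecord(acc=acc, pre=pre, rec=rec, spe=spe, f1=f1)


def segmentation_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> MetricRecord:
    """JSI, DC and pixel-level ACC/PRE/REC/SPE for one mask pair."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    jsi = _rate(inter, union, "JSI")
    dc = _rate(2 * inter, int(a.sum()) + int(b.sum()), "DC")
    cls = classification_metrics(ConfusionCounts(
        tp=inter, tn=int(np.sum(~a & ~b)),
        fp=int(np.sum(a & ~b)), fn=int(np.sum(~a & b))))
    return MetricRecord(jsi=jsi, dc=dc, acc=cls.acc, pre=cls.pre,
                        rec=cls.rec, spe=cls.spe, f1=cls.f1)


def auc(scores, true_labels, positive_class=1) -> float:
    """Area under the ROC curve (trapezoidal / normalized Mann-Whitney U)."""
    from sklearn.metrics import roc_auc_score

    y = np.asarray(true_labels) == positive_class
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y.astype(int), np.asarray(scores, dtype=float)))


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def hd95(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """95th percentile of symmetric boundary-to-boundary distances (pixels)."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("hd95 requires two non-empty masks")
    ba, bb = _boundary(a), _boundary(b)
    # distance from every boundary pixel of one mask to the nearest boundary
    # pixel of the other, pooled symmetrically
    dist_to_b = ndimage.distance_transform_edt(~bb)
    dist_to_a = ndimage.distance_transform_edt(~ba)
    d = np.concatenate([dist_to_b[ba], dist_to_a[bb]])
    return float(np.percentile(d, 95))


def write_report(records: list[MetricRecord], path, exp_names=None,
                 columns=("jsi", "dc", "acc", "rec", "pre", "spe", "f1", "auc"),
                 ) -> pd.DataFrame:
    """Write a per-experiment metric table with a Mean row as CSV.

    Absent metrics are left blank and excluded from the column mean.
    """
    names = exp_names or [str(i + 1) for i in range(len(records))]
    rows = []
    for name, rec in zip(names, records):
        d = rec.as_dict()
        rows.append({"Exp": name, **{c.upper(): d[c] for c in columns}})
    df = pd.DataFrame(rows)
    mean_row = {"Exp": "Mean"}
    for c in columns:
        col = df[c.upper()].dropna()
        mean_row[c.upper()] = col.mean() if len(col) else None
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    df.to_csv(path, index=False)
    return df
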