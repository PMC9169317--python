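"""Segmentation metrics and post-processing.

Pixel metrics over a binary prediction/mask pair: sensitivity
SE = TP/(TP+FN), specificity SP = TN/(FP+TN), accuracy ACC = (TP+TN)/N,
the Dice coefficient 2Σpq/(Σp²+Σq²), mean IoU averaged over the class set
(background + vessel for binary masks), and ROC-AUC of soft predictions.
Divisions by zero are returned as NaN with a warning — never silently 0.

`remove_small_components` implements the small-object noise filter:
connected components smaller than a fraction (default 0.03%) of the total
foreground are deleted.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from skimage import measure as _skmeasure
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "metric_suite", "dice_coefficient", "mean_iou", "roc_auc",
           "remove_small_components", "evaluate_pair"]

_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """All headline metrics for one prediction/mask pair."""
    dice: float
    dice_hard: float
    mean_iou: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1); found values {vals[:5]}")
    return arr.astype(np.int64)


def _undefined(what: str) -> float:
    warnings.warn(f"{what} is undefined (division by zero); returning NaN",
                  RuntimeWarning, stacklevel=3)
    return float("nan")


def confusion_counts(pred_binary: np.ndarray, mask: np.ndarray) -> ConfusionCounts:
    """Exhaustive pixel classification of a binary prediction against a mask."""
    p = _as_binary(pred_binary, "prediction")
    m = _as_binary(mask, "mask")
    if p.shape != m.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {m.shape}")
    tp = int(((p == 1) & (m == 1)).sum())
    fp = int(((p == 1) & (m == 0)).sum())
    tn = int(((p == 0) & (m == 0)).sum())
    fn = int(((p == 0) & (m == 1)).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metric_suite(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    se = (counts.tp / (counts.tp + counts.fn)
          if counts.tp + counts.fn else _undefined("sensitivity"))
    sp = (counts.tn / (counts.fp + counts.tn)
          if counts.fp + counts.tn else _undefined("specificity"))
    acc = ((counts.tp + counts.tn) / counts.total
           if counts.total else _undefined("accuracy"))
    return se, sp, acc


def dice_coefficient(pred: np.ndarray, mask: np.ndarray) -> float:
    """Soft-capable Dice: 2Σpq / (Σp² + Σq²), epsilon-stabilised."""
    p = np.asarray(pred, dtype=np.float64)
    q = np.asarray(mask, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {q.shape}")
    num = 2.0 * float((p * q).sum()) + _EPS
    den = float((p * p).sum() + (q * q).sum()) + _EPS
    return num / den


def mean_iou(pred: np.ndarray, mask: np.ndarray, k: int = 2) -> float:
    """Mean per-class IoU_c = p_cc / (Σ_j p_cj + Σ_j p_jc − p_cc).

    Classes absent from both prediction and mask are excluded from the mean
    with a warning.
    """
    p = np.asarray(pred).astype(np.int64)
    m = np.asarray(mask).astype(np.int64)
    if p.shape != m.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {m.shape}")
    if p.min() < 0 or p.max() >= k or m.min() < 0 or m.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    conf = np.zeros((k, k), dtype=np.int64)   # conf[i, j]: true i, predicted j
    np.add.at(conf, (m.ravel(), p.ravel()), 1)
    ious = []
    for c in range(k):
        denom = conf[c, :].sum() + conf[:, c].sum() - conf[c, c]
        if denom == 0:
            warnings.warn(f"class {c} empty in both prediction and mask; "
                          "excluded from mean IoU", RuntimeWarning,
                          stacklevel=2)
            continue
        ious.append(conf[c, c] / denom)
    if not ious:
        return _undefined("mean IoU")
    return float(np.mean(ious))


def roc_auc(pred_soft: np.ndarray, mask: np.ndarray) -> float:
    """ROC area of soft scores against a binary mask (Mann–Whitney form)."""
    p = np.asarray(pred_soft, dtype=np.float64).ravel()
    m = _as_binary(mask, "mask").ravel()
    if p.shape != m.shape:
        raise ValueError("shapes differ")
    if m.min() == m.max():
        return _undefined("ROC AUC")
    return float(roc_auc_score(m, p))


def remove_small_components(mask: np.ndarray, fraction: float = 0.0003,
                            connectivity: int = 2) -> np.ndarray:
    """Delete connected components smaller than `fraction` of the total
    foreground (8-connectivity by default).  Idempotent; an empty mask is
    returned unchanged."""
    m = _as_binary(mask, "mask")
    fg = int(m.sum())
    if fg == 0:
        return m.copy()
    labels, n = _skmeasure.label(m, connectivity=connectivity,
                                 return_num=True)
    if n <= 1:
        return m.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    threshold = fraction * fg
    keep = sizes >= threshold
    keep[0] = False
    return keep[labels].astype(m.dtype)


def evaluate_pair(pred_soft: np.ndarray, mask: np.ndarray,
                  threshold: float = 0.5) -> MetricsReport:
    """Full metric report: soft Dice/AUC plus hard metrics at `threshold`."""
    p = np.asarray(pred_soft, dtype=np.float64)
    m = _as_binary(mask, "mask")
    hard = (p >= threshold).astype(np.int64)
    counts = confusion_counts(hard, m)
    se, sp, acc = metric_suite(counts)
    return MetricsReport(
        dice=dice_coefficient(p, m),
        dice_hard=dice_coefficient(hard, m),
        mean_iou=mean_iou(hard, m, k=2),
        sensitivity=se, specificity=sp, accuracy=acc,
        auc=roc_auc(p, m),
    )
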