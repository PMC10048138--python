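"""Segmentation evaluation suite.

All aggregate metrics derive from the pixel confusion matrix P, with
P[a, b] the number of pixels whose true label is a and predicted label is b
(rows = true class; every serialised matrix documents this orientation):

* global accuracy      gAcc  = trace(P) / total
* mean accuracy        aAcc  = mean_a P_aa / M_a              (M_a = row sums)
* per-class IoU        IoU_a = P_aa / (M_a + H_a - P_aa)      (H_a = col sums)
* weighted IoU         wIoU  = sum_a (M_a / total) * IoU_a

Boundary quality is scored by the boundary F1 (bfscore): boundary pixels of
a class mask (4-connectivity, image border counts as outside) are matched
between prediction and ground truth under a Euclidean distance tolerance,
by default 0.75% of the image diagonal; precision and recall use a strict
``distance < tol`` test and are combined by the harmonic mean.  Image-level
scores average the per-class F1 over classes present in either mask, and the
dataset score averages image scores over images (never pixel-pooled), so
small images and small structures count equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "global_accuracy",
    "mean_accuracy",
    "class_iou",
    "weighted_iou",
    "boundary_map",
    "bf_precision_recall",
    "bfscore",
    "image_bfscore",
    "dataset_bfscore",
    "default_boundary_tolerance",
    "per_image_report",
    "evaluate_dataset",
]

LGE_CLASS = 3


@dataclass
class ConfusionMatrix:
    """n x n integer pixel counts; rows are true class, columns predicted."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def true_totals(self) -> np.ndarray:
        """M_a: pixels whose ground-truth label is a (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def pred_totals(self) -> np.ndarray:
        """H_b: pixels predicted as b (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        idx = [f"true_{i}" for i in range(self.n_classes)]
        cols = [f"pred_{i}" for i in range(self.n_classes)]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def _as_pairs(gt, pred):
    if isinstance(gt, np.ndarray) and isinstance(pred, np.ndarray):
        return [(gt, pred)]
    return list(zip(gt, pred))


def confusion_matrix(gt, pred, n_classes: int = 4) -> ConfusionMatrix:
    """Accumulate exact pixel counts over one or many (gt, pred) mask pairs."""
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for i, (g, p) in enumerate(_as_pairs(gt, pred)):
        g, p = np.asarray(g), np.asarray(p)
        if g.shape != p.shape:
            raise ValueError(
                f"image {i}: ground truth {g.shape} and prediction {p.shape} differ")
        if g.size and (g.max() >= n_classes or p.max() >= n_classes):
            raise ValueError(f"image {i}: labels exceed n_classes={n_classes}")
        counts += np.bincount(
            (g.ravel() * n_classes + p.ravel()).astype(np.int64),
            minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    return ConfusionMatrix(counts)


def global_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of all pixels classified correctly."""
    if cm.total == 0:
        raise ValueError("global accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def mean_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recall; classes absent from the ground
    truth are skipped (with a warning) and the class count reduced."""
    m = cm.true_totals
    present = m > 0
    if not present.any():
        raise ValueError("mean accuracy undefined: no class present in ground truth")
    if not present.all():
        logger.warning("mean_accuracy: skipping %d class(es) absent from ground truth",
                       int((~present).sum()))
    diag = np.diag(cm.counts)[present]
    return float(np.mean(diag / m[present]))


def class_iou(cm: ConfusionMatrix, a: int) -> float:
    """P_aa / (M_a + H_a - P_aa); NaN when the class is absent from both."""
    paa = cm.counts[a, a]
    denom = cm.true_totals[a] + cm.pred_totals[a] - paa
    if denom == 0:
        return float("nan")
    return float(paa / denom)


def weighted_iou(cm: ConfusionMatrix) -> float:
    """Per-class IoU weighted by each class's true-pixel share."""
    if cm.total == 0:
        raise ValueError("weighted IoU undefined for an empty confusion matrix")
    total = cm.total
    out = 0.0
    for a in range(cm.n_classes):
        m_a = cm.true_totals[a]
        if m_a == 0:
            continue
        out += (m_a / total) * class_iou(cm, a)
    return float(out)


# ---------------------------------------------------------------------------
# boundary F1
# ---------------------------------------------------------------------------


def boundary_map(mask) -> np.ndarray:
    """Boolean map of mask pixels with a 4-neighbour outside the mask.

    The image border counts as outside, so a full-image mask has a one-pixel
    boundary frame.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] &
                padded[1:-1, :-2] & padded[1:-1, 2:])
    return mask & ~interior


def default_boundary_tolerance(shape) -> float:
    """0.75% of the image diagonal, in pixels (not rounded)."""
    h, w = shape[-2], shape[-1]
    return 0.0075 * float(np.hypot(h, w))


def bf_precision_recall(pred_boundary, gt_boundary, tol: float):
    """Fraction of each boundary within strict distance ``tol`` of the other.

    Empty prediction boundary gives precision 0; empty ground-truth boundary
    gives recall 0.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    bp = np.asarray(pred_boundary, dtype=bool)
    bg = np.asarray(gt_boundary, dtype=bool)
    precision = 0.0
    recall = 0.0
    if bp.any():
        dist_to_gt = (distance_transform_edt(~bg) if bg.any()
                      else np.full(bp.shape, np.inf))
        precision = float(np.mean(dist_to_gt[bp] < tol))
    if bg.any():
        dist_to_pred = (distance_transform_edt(~bp) if bp.any()
                        else np.full(bg.shape, np.inf))
        recall = float(np.mean(dist_to_pred[bg] < tol))
    return precision, recall


def bfscore(gt, pred, o: int, tol: float | None = None) -> float:
    """Boundary F1 of class ``o``: harmonic mean of boundary precision/recall.

    Returns NaN when the class is absent from both masks (not scorable) and
    0 when precision + recall is zero.
    """
    gt, pred = np.asarray(gt), np.asarray(pred)
    if tol is None:
        tol = default_boundary_tolerance(gt.shape)
    gm, pm = gt == o, pred == o
    if not gm.any() and not pm.any():
        return float("nan")
    p, r = bf_precision_recall(boundary_map(pm), boundary_map(gm), tol)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def image_bfscore(gt, pred, tol: float | None = None, n_classes: int = 4) -> float:
    """Mean per-class boundary F1 over classes present in either mask."""
    scores = [bfscore(gt, pred, o, tol) for o in range(n_classes)]
    scores = [s for s in scores if not np.isnan(s)]
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def dataset_bfscore(pairs, tol: float | None = None, n_classes: int = 4) -> float:
    """Mean of image-level boundary F1 over images (never pixel-pooled)."""
    scores = []
    for i, (g, p) in enumerate(pairs):
        s = image_bfscore(g, p, tol, n_classes)
        if np.isnan(s):
            logger.warning("dataset_bfscore: image %d has no scorable class; excluded", i)
            continue
        scores.append(s)
    if not scores:
        raise ValueError("no image with a scorable class")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Dataset-level metrics plus the per-image table."""

    confusion: ConfusionMatrix
    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    dataset_bfscore: float
    per_class_accuracy: np.ndarray
    per_class_iou: np.ndarray
    per_class_bfscore: np.ndarray
    per_image: pd.DataFrame

    def summary(self) -> dict:
        return {
            "global_accuracy": self.global_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "mean_iou": self.mean_iou,
            "weighted_iou": self.weighted_iou,
            "dataset_bfscore": self.dataset_bfscore,
            "per_class_accuracy": [None if np.isnan(v) else float(v)
                                   for v in self.per_class_accuracy],
            "per_class_iou": [None if np.isnan(v) else float(v)
                              for v in self.per_class_iou],
            "per_class_bfscore": [None if np.isnan(v) else float(v)
                                  for v in self.per_class_bfscore],
        }


def per_image_report(pairs, tol: float | None = None, n_classes: int = 4,
                     image_ids=None) -> pd.DataFrame:
    """Per-image table: gAcc, aAcc, bfscore, LGE true positives and LGE
    predicted positives (true positives plus false alarms)."""
    pairs = list(pairs)
    if image_ids is None:
        image_ids = list(range(len(pairs)))
    rows = []
    for img_id, (g, p) in zip(image_ids, pairs):
        g, p = np.asarray(g), np.asarray(p)
        cm = confusion_matrix(g, p, n_classes)
        rows.append({
            "image_id": img_id,
            "global_accuracy": global_accuracy(cm),
            "mean_accuracy": mean_accuracy(cm),
            "bfscore": image_bfscore(g, p, tol, n_classes),
            "lge_true_positives": int(np.sum((g == LGE_CLASS) & (p == LGE_CLASS))),
            "lge_predicted_positives": int(np.sum(p == LGE_CLASS)),
        })
    return pd.DataFrame(rows)


def evaluate_dataset(pairs, tol: float | None = None, n_classes: int = 4,
                     image_ids=None) -> MetricsReport:
    """Full evaluation of a collection of (ground truth, prediction) pairs."""
    pairs = [(np.asarray(g), np.asarray(p)) for g, p in pairs]
    cm = confusion_matrix([g for g, _ in pairs], [p for _, p in pairs], n_classes)
    per_class_acc = np.array([
        cm.counts[a, a] / cm.true_totals[a] if cm.true_totals[a] else np.nan
        for a in range(n_classes)])
    per_class_iou = np.array([class_iou(cm, a) for a in range(n_classes)])
    per_class_bf = []
    for o in range(n_classes):
        vals = [bfscore(g, p, o, tol) for g, p in pairs]
        vals = [v for v in vals if not np.isnan(v)]
        per_class_bf.append(np.mean(vals) if vals else np.nan)
    return MetricsReport(
        confusion=cm,
        global_accuracy=global_accuracy(cm),
        mean_accuracy=mean_accuracy(cm),
        mean_iou=float(np.nanmean(per_class_iou)),
        weighted_iou=weighted_iou(cm),
        dataset_bfscore=dataset_bfscore(pairs, tol, n_classes),
        per_class_accuracy=per_class_acc,
        per_class_iou=per_class_iou,
        per_class_bfscore=np.array(per_class_bf),
        per_image=per_image_report(pairs, tol, n_classes, image_ids),
    )
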