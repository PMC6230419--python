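"""Evaluation suite for 4-class tissue segmentations.

Covers the standard overlap measures (Dice 2|x∩y|/(|x|+|y|), Jaccard/IoU
|x∩y|/|x∪y|, related by J = D/(2−D)), the confusion-matrix statistics
(global/mean accuracy, mean and frequency-weighted IoU), intensity MSE on a
0–255 gray rendering of the label maps, and a boundary-F1 (BF) score that
matches boundary pixels within a distance tolerance.  Per-class Dice/Jaccard
are computed one-vs-rest; the headline means average the three tissue
classes (CSF, GM, WM), excluding background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

N_CLASSES = 4
CLASS_NAMES = ("background", "CSF", "GM", "WM")
TISSUE_CLASSES = (1, 2, 3)
GRAY_LEVELS = np.array([0, 85, 170, 255])  # round(255*c/3)


def _check_same_shape(x, y, what="inputs"):
    if x.shape != y.shape:
        raise ValueError(f"{what} must have the same shape, got {x.shape} vs {y.shape}")


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity 2|x∩y|/(|x|+|y|); 1.0 when both masks are empty."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    _check_same_shape(x, y, "masks")
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard similarity |x∩y|/|x∪y|; 1.0 when both masks are empty."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    _check_same_shape(x, y, "masks")
    union = int((x | y).sum())
    if union == 0:
        return 1.0
    return int((x & y).sum()) / union


def label_to_gray(labels: np.ndarray) -> np.ndarray:
    """Render a label map on a 0–255 gray scale: class c -> round(255*c/3)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 3:
        raise ValueError(f"label values outside {{0,1,2,3}} (max={labels.max()})")
    return GRAY_LEVELS[labels.astype(np.int64)]


def gray_to_label(gray: np.ndarray) -> np.ndarray:
    """Inverse of :func:`label_to_gray` (exact lookup)."""
    gray = np.asarray(gray)
    out = np.searchsorted(GRAY_LEVELS, gray)
    if out.max(initial=0) > 3 or not np.array_equal(GRAY_LEVELS[out], gray):
        raise ValueError("gray image contains values outside {0,85,170,255}")
    return out.astype(np.uint8)


def mse(image: np.ndarray, image_ref: np.ndarray) -> float:
    """Mean squared intensity error (1/(M*N)) * sum (I - I')^2."""
    image = np.asarray(image, dtype=np.float64)
    image_ref = np.asarray(image_ref, dtype=np.float64)
    _check_same_shape(image, image_ref, "images")
    return float(np.mean((image - image_ref) ** 2))


def confusion_matrix(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """4x4 counts; rows are true class, columns predicted class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_shape(pred, truth, "label maps")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= N_CLASSES:
            raise ValueError(f"{name} contains labels outside {{0,..,{N_CLASSES - 1}}}")
    idx = truth.astype(np.int64).ravel() * N_CLASSES + pred.astype(np.int64).ravel()
    return np.bincount(idx, minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)


def derived_statistics(cm: np.ndarray, class_frequencies=None) -> dict:
    """Accuracy/IoU statistics from a confusion matrix.

    global accuracy = trace/total; per-class accuracy = diag/row sum;
    per-class IoU = diag / (row + col − diag); means average the classes
    present (row sum > 0); weighted IoU weights by true-class frequency.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    present = row > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(present, diag / np.where(row > 0, row, 1), np.nan)
        union = row + col - diag
        iou = np.where(union > 0, diag / np.where(union > 0, union, 1), np.nan)
    if class_frequencies is None:
        class_frequencies = row / total
    freq = np.asarray(class_frequencies, dtype=np.float64)
    return {
        "global_accuracy": float(diag.sum() / total),
        "class_accuracy": acc,
        "mean_accuracy": float(np.nanmean(acc[present])),
        "class_iou": iou,
        "mean_iou": float(np.nanmean(iou[present])),
        "weighted_iou": float(np.nansum(freq[present] * iou[present])),
    }


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with a 4-neighbour outside the mask; the
    image border counts as outside (so a full-canvas mask still has a rim)."""
    mask = np.asarray(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def default_bf_tolerance(shape: tuple) -> int:
    """0.75% of the image diagonal, rounded up and at least one pixel."""
    diag = float(np.hypot(*shape))
    return max(1, int(np.ceil(0.0075 * diag)))


def bf_score(pred: np.ndarray, truth: np.ndarray, tolerance: float | None = None) -> float:
    """Boundary F1: precision/recall of boundary pixels matched within
    ``tolerance`` (Euclidean pixels); 2PR/(P+R), 0 when P+R = 0, and 1 when
    neither mask has a boundary (nothing to match on either side)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    _check_same_shape(pred, truth, "masks")
    if tolerance is None:
        tolerance = default_bf_tolerance(pred.shape)
    bp = _boundary(pred)
    bt = _boundary(truth)
    if not bp.any() and not bt.any():
        return 1.0
    if not bp.any() or not bt.any():
        return 0.0
    dist_to_truth = ndimage.distance_transform_edt(~bt)
    dist_to_pred = ndimage.distance_transform_edt(~bp)
    precision = float((dist_to_truth[bp] <= tolerance).mean())
    recall = float((dist_to_pred[bt] <= tolerance).mean())
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class SegmentationReport:
    """Per-class and aggregate metrics for one prediction/truth pair."""

    class_names: tuple = CLASS_NAMES
    dice: dict = field(default_factory=dict)
    jaccard: dict = field(default_factory=dict)
    iou: dict = field(default_factory=dict)
    accuracy: dict = field(default_factory=dict)
    bf: dict = field(default_factory=dict)
    mean_tissue_dice: float = float("nan")
    mean_tissue_jaccard: float = float("nan")
    global_accuracy: float = float("nan")
    mean_accuracy: float = float("nan")
    mean_iou: float = float("nan")
    weighted_iou: float = float("nan")
    mean_bf: float = float("nan")
    mse: float = float("nan")
    confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        def clean(v):
            return None if (isinstance(v, float) and np.isnan(v)) else v
        return {
            "per_class": {
                name: {
                    "dice": clean(self.dice[name]),
                    "jaccard": clean(self.jaccard[name]),
                    "iou": clean(self.iou[name]),
                    "accuracy": clean(self.accuracy[name]),
                    "bf_score": clean(self.bf[name]),
                }
                for name in self.class_names
            },
            "aggregate": {
                "mean_tissue_dice": clean(self.mean_tissue_dice),
                "mean_tissue_jaccard": clean(self.mean_tissue_jaccard),
                "global_accuracy": clean(self.global_accuracy),
                "mean_accuracy": clean(self.mean_accuracy),
                "mean_iou": clean(self.mean_iou),
                "weighted_iou": clean(self.weighted_iou),
                "mean_bf_score": clean(self.mean_bf),
                "mse_gray": clean(self.mse),
            },
            "confusion_matrix": self.confusion.tolist() if self.confusion is not None else None,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        """Plain-text table: one metric row per tissue class plus the mean."""
        lines = [f"{'Parameter':<20}{'CSF':>8}{'GM':>8}{'WM':>8}{'Mean':>8}"]
        for label, d in (("Dice similarity", self.dice), ("Jaccard similarity", self.jaccard)):
            vals = [d[CLASS_NAMES[c]] for c in TISSUE_CLASSES]
            cells = "".join(f"{v:>8.2f}" for v in vals)
            lines.append(f"{label:<20}{cells}{np.mean(vals):>8.2f}")
        lines.append(f"{'Mean squared error':<20}{'—':>8}{'—':>8}{'—':>8}{self.mse:>8.2f}")
        return "\n".join(lines)


def evaluate(pred: np.ndarray, truth: np.ndarray, bf_tolerance: float | None = None) -> SegmentationReport:
    """Assemble the full report for one predicted/true label-map pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_shape(pred, truth, "label maps")
    cm = confusion_matrix(pred, truth)
    stats = derived_statistics(cm)
    report = SegmentationReport(confusion=cm)
    for c, name in enumerate(CLASS_NAMES):
        pm = pred == c
        tm = truth == c
        report.dice[name] = dice(pm, tm)
        report.jaccard[name] = jaccard(pm, tm)
        report.iou[name] = float(stats["class_iou"][c])
        report.accuracy[name] = float(stats["class_accuracy"][c])
        report.bf[name] = bf_score(pm, tm, bf_tolerance)
    report.mean_tissue_dice = float(np.mean([report.dice[CLASS_NAMES[c]] for c in TISSUE_CLASSES]))
    report.mean_tissue_jaccard = float(
        np.mean([report.jaccard[CLASS_NAMES[c]] for c in TISSUE_CLASSES])
    )
    report.global_accuracy = stats["global_accuracy"]
    report.mean_accuracy = stats["mean_accuracy"]
    report.mean_iou = stats["mean_iou"]
    report.weighted_iou = stats["weighted_iou"]
    report.mean_bf = float(np.mean([report.bf[n] for n in CLASS_NAMES]))
    report.mse = mse(label_to_gray(pred), label_to_gray(truth))
    return report


def evaluate_set(pred_truth_pairs, bf_tolerance: float | None = None) -> dict:
    """Per-item reports plus aggregates over a test set (pooled confusion
    matrix; unweighted means of the per-item tissue Dice/Jaccard)."""
    reports = []
    pooled = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for pred, truth in pred_truth_pairs:
        rep = evaluate(pred, truth, bf_tolerance)
        pooled += rep.confusion
        reports.append(rep)
    if not reports:
        raise ValueError("no prediction/truth pairs to evaluate")
    stats = derived_statistics(pooled)
    return {
        "per_image": reports,
        "pooled_confusion": pooled,
        "mean_tissue_dice": float(np.mean([r.mean_tissue_dice for r in reports])),
        "mean_tissue_jaccard": float(np.mean([r.mean_tissue_jaccard for r in reports])),
        "global_accuracy": stats["global_accuracy"],
        "mean_accuracy": stats["mean_accuracy"],
        "mean_iou": stats["mean_iou"],
        "weighted_iou": stats["weighted_iou"],
    }
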