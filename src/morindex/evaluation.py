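"""Pixel-level segmentation scoring: accuracy, Dice, mean IoU.

All three scores are derived from one-vs-rest confusion counts computed per
class over a pair of label rasters:

    Accuracy = (TP + TN) / (TP + TN + FP + FN)
    Dice     = 2 TP / (2 TP + FP + FN)
    MIoU     = mean over the k+1 categories (background included) of
               TP / (TP + FP + FN)

An auxiliary instance-level greedy IoU matcher is provided for synthetic
recovery checks; it is not one of the pixel metrics above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ConfusionCounts",
    "SegScores",
    "confusion_counts",
    "accuracy",
    "dice",
    "miou",
    "seg_scores",
    "match_instances",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel confusion counts for each class.

    For every class c: TP_c + FP_c + TN_c + FN_c equals the raster size.
    """

    classes: tuple
    tp: dict
    fp: dict
    tn: dict
    fn: dict
    total: int

    def for_class(self, c) -> tuple[int, int, int, int]:
        return self.tp[c], self.fp[c], self.tn[c], self.fn[c]


@dataclass(frozen=True)
class SegScores:
    accuracy: float
    dice: float | None
    miou: float


def confusion_counts(pred, truth, classes) -> ConfusionCounts:
    """Count per-class one-vs-rest TP/FP/TN/FN over two label rasters."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidInputError("pred and truth rasters differ in shape")
    classes = tuple(classes)
    known = np.isin(pred, classes) & np.isin(truth, classes)
    if not known.all():
        raise InvalidInputError("raster contains labels outside the class list")
    total = pred.size
    tp, fp, tn, fn = {}, {}, {}, {}
    for c in classes:
        p = pred == c
        t = truth == c
        tp[c] = int(np.count_nonzero(p & t))
        fp[c] = int(np.count_nonzero(p & ~t))
        fn[c] = int(np.count_nonzero(~p & t))
        tn[c] = total - tp[c] - fp[c] - fn[c]
    return ConfusionCounts(classes, tp, fp, tn, fn, total)


def accuracy(counts: ConfusionCounts, positive_class) -> float:
    """(TP + TN) / (TP + TN + FP + FN) for one class against the rest."""
    tp, fp, tn, fn = counts.for_class(positive_class)
    total = tp + fp + tn + fn
    if total == 0:
        raise InvalidInputError("zero total pixels")
    return (tp + tn) / total


def dice(counts: ConfusionCounts, positive_class) -> float | None:
    """2 TP / (2 TP + FP + FN); None when the class is empty in both rasters."""
    tp, fp, _, fn = counts.for_class(positive_class)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return None
    return 2 * tp / denom


def miou(counts: ConfusionCounts, absent: str = "exclude") -> float:
    """Mean over classes of TP / (TP + FP + FN).

    ``absent`` controls classes missing from both rasters: "exclude" drops
    them (with a warning), "one" scores them as a perfect 1.0.
    """
    if absent not in ("exclude", "one"):
        raise InvalidInputError("absent must be 'exclude' or 'one'")
    ious = []
    for c in counts.classes:
        tp, fp, _, fn = counts.for_class(c)
        denom = tp + fp + fn
        if denom == 0:
            if absent == "one":
                ious.append(1.0)
            else:
                warnings.warn(
                    f"class {c!r} absent from both rasters; excluded from MIoU",
                    stacklevel=2,
                )
            continue
        ious.append(tp / denom)
    if not ious:
        raise InvalidInputError("no class present in either raster")
    return float(np.mean(ious))


def seg_scores(pred, truth, classes, positive_class=None,
               absent: str = "exclude") -> SegScores:
    """Convenience wrapper computing all three pixel scores at once.

    ``positive_class`` (for accuracy and Dice) defaults to the last listed
    class, the foreground by the background-first convention.
    """
    counts = confusion_counts(pred, truth, classes)
    if positive_class is None:
        positive_class = counts.classes[-1]
    return SegScores(
        accuracy=accuracy(counts, positive_class),
        dice=dice(counts, positive_class),
        miou=miou(counts, absent=absent),
    )


def match_instances(pred_raster, truth_raster, iou_threshold: float = 0.5):
    """Greedy one-to-one instance matching by IoU (highest first).

    Returns ``(matches, n_pred, n_truth)`` where matches is a list of
    ``(pred_id, truth_id, iou)``.  Recall = len(matches) / n_truth.
    """
    pred_raster = np.asarray(pred_raster)
    truth_raster = np.asarray(truth_raster)
    if pred_raster.shape != truth_raster.shape:
        raise InvalidInputError("instance rasters differ in shape")
    pred_ids = np.unique(pred_raster)
    pred_ids = pred_ids[pred_ids > 0]
    truth_ids = np.unique(truth_raster)
    truth_ids = truth_ids[truth_ids > 0]
    pairs = []
    for t in truth_ids:
        tmask = truth_raster == t
        overlapping = np.unique(pred_raster[tmask])
        for p in overlapping[overlapping > 0]:
            pmask = pred_raster == p
            inter = np.count_nonzero(tmask & pmask)
            union = np.count_nonzero(tmask | pmask)
            iou = inter / union
            if iou >= iou_threshold:
                pairs.append((iou, int(p), int(t)))
    pairs.sort(reverse=True)
    used_p, used_t, matches = set(), set(), []
    for iou, p, t in pairs:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        matches.append((p, t, iou))
    return matches, len(pred_ids), len(truth_ids)
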