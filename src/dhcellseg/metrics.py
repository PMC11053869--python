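"""Instance detection/segmentation evaluation: matching, P/R/Dice, AP, PQ.

Predictions and ground truths are binary masks on a shared image grid.
Matching at IoU threshold >= 0.5 is unique (two masks above 0.5 IoU with the
same target cannot coexist), so any reasonable algorithm returns the same
one-to-one assignment; below 0.5 predictions claim truths greedily in
descending confidence order.

Metric conventions:

* precision = TP/(TP+FP), recall = TP/(TP+FN), count-based
  dice = 2TP/(2TP+FN+FP); a zero denominator yields 0 so evaluation is
  total over degenerate scenes.
* AP is the area under the all-point-interpolated precision-recall curve
  obtained by sweeping the confidence threshold at fixed IoU; an optional
  COCO-style mode averages over IoU in {0.50, 0.55, ..., 0.95}.
* PQ = DQ * SQ with DQ = TP/(TP + FN/2 + FP/2) and SQ the mean IoU over
  matched pairs (0 when nothing matches).

A pixel-level dice (2|A∩B|/(|A|+|B|) averaged over matched pairs) is exposed
separately from the count-based one; segmentation benchmarks report either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MatchTable",
    "MetricsReport",
    "mask_iou",
    "match_instances",
    "precision_recall_dice",
    "pixel_dice",
    "average_precision",
    "panoptic_quality",
    "evaluate",
]


def _as_bool_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool)


def mask_iou(a, b) -> float:
    """Intersection over union of two binary masks; 0 when both empty."""
    a, b = _as_bool_mask(a), _as_bool_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def _mask_of(p):
    """Accept either a bare mask or an object with a .mask attribute."""
    return getattr(p, "mask", p)


def _score_of(p, default=1.0):
    return float(getattr(p, "score", default))


@dataclass
class MatchTable:
    """One-to-one assignment of predictions to ground truths at an IoU cut."""

    pairs: list[tuple[int, int, float]]  # (prediction idx, truth idx, IoU)
    unmatched_predictions: list[int]
    unmatched_truths: list[int]
    iou_threshold: float
    tn: int = 0  # recorded for completeness; unused by the metric formulas

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_predictions)

    @property
    def fn(self) -> int:
        return len(self.unmatched_truths)


def match_instances(
    predictions: Sequence, truths: Sequence, iou_threshold: float = 0.5
) -> MatchTable:
    """Match predicted to ground-truth instances one-to-one above the cut.

    Predictions are processed in descending score order (score attribute if
    present, else 1), each taking its highest-IoU still-free truth with
    IoU > threshold.  For thresholds >= 0.5 this equals the optimal
    assignment because matches above 0.5 are unique.
    """
    pred_masks = [_as_bool_mask(_mask_of(p)) for p in predictions]
    truth_masks = [_as_bool_mask(_mask_of(t)) for t in truths]
    for m in pred_masks + truth_masks:
        if truth_masks and m.shape != truth_masks[0].shape:
            raise ValueError("all masks must share the image dimensions")
    order = sorted(
        range(len(pred_masks)),
        key=lambda i: -_score_of(predictions[i]),
    )
    iou = np.zeros((len(pred_masks), len(truth_masks)))
    for i, pm in enumerate(pred_masks):
        for j, tm in enumerate(truth_masks):
            iou[i, j] = mask_iou(pm, tm)
    taken = np.zeros(len(truth_masks), dtype=bool)
    pairs = []
    unmatched_preds = []
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j in range(len(truth_masks)):
            if not taken[j] and iou[i, j] > best_iou:
                best_j, best_iou = j, iou[i, j]
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((i, best_j, float(iou[i, best_j])))
        else:
            unmatched_preds.append(i)
    unmatched_truths = [j for j in range(len(truth_masks)) if not taken[j]]
    return MatchTable(
        pairs=pairs,
        unmatched_predictions=unmatched_preds,
        unmatched_truths=unmatched_truths,
        iou_threshold=iou_threshold,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def precision_recall_dice(table: MatchTable) -> tuple[float, float, float]:
    """(precision, recall, count-based dice) from a match table."""
    tp, fp, fn = table.tp, table.fp, table.fn
    return (
        _safe_div(tp, tp + fp),
        _safe_div(tp, tp + fn),
        _safe_div(2 * tp, 2 * tp + fn + fp),
    )


def pixel_dice(predictions: Sequence, truths: Sequence, table: MatchTable) -> float:
    """Mean pixel-level dice 2|A∩B|/(|A|+|B|) over matched pairs; 0 if none."""
    if not table.pairs:
        return 0.0
    vals = []
    for i, j, _ in table.pairs:
        a = _as_bool_mask(_mask_of(predictions[i]))
        b = _as_bool_mask(_mask_of(truths[j]))
        denom = a.sum() + b.sum()
        vals.append(_safe_div(2.0 * np.logical_and(a, b).sum(), denom))
    return float(np.mean(vals))


def average_precision(
    predictions: Sequence,
    truths: Sequence,
    iou_threshold: float = 0.5,
    iou_thresholds: Optional[Sequence[float]] = None,
) -> tuple[float, list[tuple[float, float]]]:
    """AP by confidence-threshold sweeping at fixed IoU, plus the PR curve.

    Returns the area under the all-point-interpolated precision-recall
    curve and its (recall, precision) points.  With ``iou_thresholds`` the
    AP is averaged over those IoU cuts (COCO style) and the curve returned
    is the one at the first threshold.
    """
    if iou_thresholds is not None:
        aps, curve0 = [], None
        for k, t in enumerate(iou_thresholds):
            ap, curve = average_precision(predictions, truths, iou_threshold=t)
            aps.append(ap)
            if k == 0:
                curve0 = curve
        return float(np.mean(aps)) if aps else 0.0, curve0 or []
    n_truth = len(truths)
    if n_truth == 0 or len(predictions) == 0:
        return 0.0, []
    order = sorted(range(len(predictions)),
                   key=lambda i: -_score_of(predictions[i]))
    truth_masks = [_as_bool_mask(_mask_of(t)) for t in truths]
    taken = np.zeros(n_truth, dtype=bool)
    hits = []
    for i in order:
        pm = _as_bool_mask(_mask_of(predictions[i]))
        best_j, best_iou = -1, iou_threshold
        for j, tm in enumerate(truth_masks):
            if not taken[j]:
                v = mask_iou(pm, tm)
                if v > best_iou:
                    best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            hits.append(1)
        else:
            hits.append(0)
    tp_cum = np.cumsum(hits)
    fp_cum = np.cumsum([1 - h for h in hits])
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # all-point interpolation: precision envelope from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, prec_env):
        ap += (r - prev_r) * p
        prev_r = r
    curve = list(zip(recall.tolist(), precision.tolist()))
    return float(ap), curve


def panoptic_quality(
    predictions: Sequence, truths: Sequence, iou_threshold: float = 0.5
) -> tuple[float, float, float]:
    """(PQ, DQ, SQ): detection quality times mean matched IoU."""
    table = match_instances(predictions, truths, iou_threshold)
    dq = _safe_div(table.tp, table.tp + 0.5 * table.fn + 0.5 * table.fp)
    sq = float(np.mean([iou for _, _, iou in table.pairs])) if table.pairs else 0.0
    return dq * sq, dq, sq


@dataclass
class MetricsReport:
    """All metrics of one evaluation run, with the PR curve points."""

    precision: float
    recall: float
    dice: float
    dice_pixel: float
    ap: float
    dq: float
    sq: float
    pq: float
    curve: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "dice": self.dice,
            "dice_pixel": self.dice_pixel,
            "ap": self.ap,
            "dq": self.dq,
            "sq": self.sq,
            "pq": self.pq,
            "curve": [list(p) for p in self.curve],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path) -> None:
        d = self.to_dict()
        d.pop("curve")
        with open(path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join(f"{v:.6f}" for v in d.values()) + "\n")


def evaluate(
    predictions: Sequence, truths: Sequence, iou_threshold: float = 0.5
) -> MetricsReport:
    """Full evaluation of one scene (or a pooled set of scenes)."""
    table = match_instances(predictions, truths, iou_threshold)
    precision, recall, dice = precision_recall_dice(table)
    ap, curve = average_precision(predictions, truths, iou_threshold)
    pq, dq, sq = panoptic_quality(predictions, truths, iou_threshold)
    return MetricsReport(
        precision=precision,
        recall=recall,
        dice=dice,
        dice_pixel=pixel_dice(predictions, truths, table),
        ap=ap,
        dq=dq,
        sq=sq,
        pq=pq,
        curve=curve,
    )
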