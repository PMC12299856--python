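"""Precision, recall, AP and mAP for single-class detection.

Matching is the standard greedy protocol: detections sorted by confidence
descending, each claims the unmatched ground-truth box of highest IoU at
or above the threshold (one-to-one).  AP is the area under the monotone
(non-increasing) precision envelope over recall, i.e. all-point
interpolation as used by modern YOLO-family evaluators.

``map50`` is AP at IoU 0.50; ``map50_90`` averages AP over the IoU
threshold grid {0.50, 0.55, ..., 0.90} (inclusive, 9 thresholds); the
COCO-style 0.50-0.95 grid is available by passing custom thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxgeom import Box, iou

__all__ = [
    "Detection",
    "EvalResult",
    "DEFAULT_THRESHOLDS",
    "match_detections",
    "pr_curve_and_ap",
    "evaluate",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.901, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """One predicted box with a confidence in [0, 1]."""

    image_id: str
    box: Box
    confidence: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.confidence) and 0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be finite in [0, 1], got {self.confidence}")


@dataclass
class EvalResult:
    """Per-threshold APs, the summary mAPs and the final operating point.

    ``match_table`` maps each IoU threshold to a per-detection list of the
    matched ground-truth index or None, in confidence-ranked order.
    """

    ap_per_threshold: dict[float, float]
    map50: float
    map50_90: float
    precision: float
    recall: float
    n_detections: int
    n_gt: int
    match_table: dict[float, list[int | None]] = field(default_factory=dict)
    zero_prediction_flag: bool = False


def _rank(dets: Sequence[Detection]) -> list[int]:
    """Confidence-descending order; ties keep input order (stable sort)."""
    return sorted(range(len(dets)), key=lambda i: -dets[i].confidence)


def match_detections(dets: Sequence[Detection], gts: Sequence[Box],
                     iou_threshold: float,
                     ) -> tuple[np.ndarray, list[int | None]]:
    """Greedy one-to-one matching within one image.

    Returns ``(flags, matches)`` in confidence-ranked order: ``flags[i]``
    is True for a true positive; ``matches[i]`` the claimed ground-truth
    index or None.  IoU ties go to the lowest ground-truth index.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    order = _rank(dets)
    taken: set[int] = set()
    flags = np.zeros(len(dets), dtype=bool)
    matches: list[int | None] = [None] * len(dets)
    for rank_pos, det_idx in enumerate(order):
        best_iou = 0.0
        best_gt: int | None = None
        for gt_idx, gt in enumerate(gts):
            if gt_idx in taken:
                continue
            ov = iou(dets[det_idx].box, gt)
            if ov >= iou_threshold and ov > best_iou:
                best_iou = ov
                best_gt = gt_idx
        if best_gt is not None:
            taken.add(best_gt)
            flags[rank_pos] = True
            matches[rank_pos] = best_gt
    return flags, matches


def pr_curve_and_ap(flags: np.ndarray, n_gt: int
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative PR curve over the ranking and all-point-interpolated AP.

    ``flags`` are TP indicators in confidence-ranked order.  AP is 0 when
    there are no ground truths or no detections.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0 or n_gt == 0:
        return np.zeros(0), np.zeros(0), 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    precision = tp / (tp + fp)
    recall = tp / n_gt
    # monotone non-increasing envelope of precision, then area over recall
    mprec = np.concatenate(([0.0], precision, [0.0]))
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    for i in range(mprec.size - 2, -1, -1):
        mprec[i] = max(mprec[i], mprec[i + 1])
    ap = float(np.sum((mrec[1:] - mrec[:-1]) * mprec[1:]))
    return precision, recall, ap


def _group_by_image(dets: Sequence[Detection], gts: dict[str, Sequence[Box]],
                    iou_threshold: float) -> tuple[np.ndarray, list[int | None]]:
    """Match per image, then merge flags into one global confidence ranking."""
    per_image_flags: dict[str, tuple[list[int], np.ndarray, list[int | None]]] = {}
    images = {d.image_id for d in dets} | set(gts)
    global_rows: list[tuple[float, int, bool, int | None]] = []
    counter = 0
    for img in sorted(images):
        img_dets = [d for d in dets if d.image_id == img]
        flags, matches = match_detections(img_dets, list(gts.get(img, [])), iou_threshold)
        order = _rank(img_dets)
        for pos, det_idx in enumerate(order):
            global_rows.append((img_dets[det_idx].confidence, counter,
                                bool(flags[pos]), matches[pos]))
            counter += 1
    global_rows.sort(key=lambda t: (-t[0], t[1]))
    return (np.array([r[2] for r in global_rows], dtype=bool),
            [r[3] for r in global_rows])


def evaluate(dets: Sequence[Detection],
             gts: Sequence[Box] | dict[str, Sequence[Box]],
             thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> EvalResult:
    """Score detections against ground truth over a threshold grid.

    ``gts`` is either a flat list (single-image evaluation: every
    detection's image_id is ignored) or a dict image_id -> boxes.
    """
    if not isinstance(gts, dict):
        image_ids = {d.image_id for d in dets}
        if len(image_ids) > 1:
            raise ValueError("flat ground-truth list requires single-image detections")
        gts = {next(iter(image_ids)) if image_ids else "img": list(gts)}
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0 and len(dets) > 0:
        warnings.warn("no ground-truth boxes: every detection is a false positive",
                      RuntimeWarning, stacklevel=2)

    ap_per: dict[float, float] = {}
    table: dict[float, list[int | None]] = {}
    final_precision = 0.0
    final_recall = 0.0
    for t in thresholds:
        flags, matches = _group_by_image(dets, gts, float(t))
        prec, rec, ap = pr_curve_and_ap(flags, n_gt)
        ap_per[float(t)] = ap
        table[float(t)] = matches
        if np.isclose(t, 0.5):
            final_precision = float(prec[-1]) if prec.size else 0.0
            final_recall = float(rec[-1]) if rec.size else 0.0
    t50 = min(ap_per, key=lambda t: abs(t - 0.5))
    return EvalResult(
        ap_per_threshold=ap_per,
        map50=ap_per[t50],
        map50_90=float(np.mean(list(ap_per.values()))),
        precision=final_precision,
        recall=final_recall,
        n_detections=len(dets),
        n_gt=n_gt,
        match_table=table,
        zero_prediction_flag=len(dets) == 0,
    )
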