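"""Evaluation protocol: IoU, per-image matching, and the aggregate report.

Metrics mirror the standard per-ROI accounting for a two-hips-per-image
detector: average/minimum IoU over ground truths (an unmatched ground truth
contributes IoU 0, keeping the totals equal to the number of annotated
ROIs), average/minimum confidence over the reported detections, the count of
ROIs below the IoU 0.5 cutoff, and AP50 with all-points (precision
envelope) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import BoxAnnotation

__all__ = [
    "iou",
    "pairwise_iou",
    "match_for_eval",
    "ap50",
    "evaluate",
    "EvalReport",
    "MatchedPair",
]


def _corners(box) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) from a BoxAnnotation, Detection, or (cx, cy, w, h)."""
    if hasattr(box, "corners"):
        return box.corners()
    cx, cy, w, h = (float(v) for v in box)
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two axis-aligned boxes.

    Continuous coordinates, no pixel discretization.  Accepts box objects
    with a ``corners()`` method or (cx, cy, w, h) quadruples.
    """
    ax0, ay0, ax1, ay1 = _corners(box_a)
    bx0, by0, bx1, by1 = _corners(box_b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    return inter / (area_a + area_b - inter)


def pairwise_iou(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(N, M) IoU matrix for two (., 4) arrays of (cx, cy, w, h) boxes."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    ax0, ay0 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax1, ay1 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx0, by0 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx1, by1 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax1[:, None], bx1) - np.maximum(ax0[:, None], bx0), 0, None)
    ih = np.clip(np.minimum(ay1[:, None], by1) - np.maximum(ay0[:, None], by0), 0, None)
    inter = iw * ih
    area_a = (a[:, 2] * a[:, 3])[:, None]
    area_b = b[:, 2] * b[:, 3]
    union = area_a + area_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


@dataclass(frozen=True)
class MatchedPair:
    image_id: str
    gt_index: int  # index into the per-image gt list
    det_index: int | None  # None for an unmatched ground truth
    iou: float
    confidence: float | None


def match_for_eval(
    gts: Sequence[BoxAnnotation], detections: Sequence
) -> list[MatchedPair]:
    """Greedy 1-1 pairing of ground truths and detections within one image.

    Repeatedly pairs the remaining (gt, det) with the highest IoU; ties are
    broken by higher detection confidence, then lower gt index.  Leftover
    ground truths are recorded unmatched (IoU 0).
    """
    image_id = gts[0].image_id if gts else ""
    candidates = []
    for gi, g in enumerate(gts):
        for di, d in enumerate(detections):
            candidates.append((iou(g, (d.cx, d.cy, d.side, d.side)), float(d.confidence), gi, di))
    # sort: IoU desc, confidence desc, gt index asc, det index asc
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used_g: set[int] = set()
    used_d: set[int] = set()
    pairs: list[MatchedPair] = []
    for ov, conf, gi, di in candidates:
        if gi in used_g or di in used_d:
            continue
        used_g.add(gi)
        used_d.add(di)
        pairs.append(MatchedPair(image_id, gi, di, ov, conf))
    for gi in range(len(gts)):
        if gi not in used_g:
            pairs.append(MatchedPair(image_id, gi, None, 0.0, None))
    pairs.sort(key=lambda p: p.gt_index)
    return pairs


def ap50(
    gts: Sequence[BoxAnnotation], detections: Sequence, iou_thresh: float = 0.5
) -> float:
    """Average precision at an IoU cutoff (default 0.5).

    Detections are ranked by confidence across images; each is a true
    positive if it reaches the cutoff against a still-unclaimed ground truth
    in its image (claiming the highest-IoU one), else a false positive.
    The AP is the area under the precision-recall curve using all-points
    interpolation (the precision envelope).
    """
    if not gts:
        raise ValueError("ap50 requires at least one ground truth")
    if not detections:
        return 0.0
    gt_by_image: dict[str, list[int]] = {}
    for gi, g in enumerate(gts):
        gt_by_image.setdefault(g.image_id, []).append(gi)
    order = sorted(
        range(len(detections)),
        key=lambda i: (-float(detections[i].confidence), detections[i].image_id, i),
    )
    claimed: set[int] = set()
    tp = np.zeros(len(order))
    for rank, di in enumerate(order):
        d = detections[di]
        best_gi, best_ov = None, 0.0
        for gi in gt_by_image.get(d.image_id, []):
            if gi in claimed:
                continue
            ov = iou(gts[gi], (d.cx, d.cy, d.side, d.side))
            if ov >= iou_thresh and ov > best_ov:
                best_gi, best_ov = gi, ov
        if best_gi is not None:
            claimed.add(best_gi)
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / (np.arange(len(order)) + 1)
    recall = cum_tp / len(gts)
    # precision envelope: p(r) = max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(env, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


@dataclass(frozen=True)
class EvalReport:
    """Aggregate detection metrics plus the per-image match table."""

    n_images: int
    n_rois: int
    avg_iou: float
    avg_confidence: float
    min_iou: float
    min_confidence: float
    n_below_half_iou: int
    ap50: float
    matches: tuple[MatchedPair, ...] = field(default=(), repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_images": self.n_images,
                    "n_rois": self.n_rois,
                    "avg_iou": self.avg_iou,
                    "avg_confidence": self.avg_confidence,
                    "min_iou": self.min_iou,
                    "min_confidence": self.min_confidence,
                    "n_below_half_iou": self.n_below_half_iou,
                    "ap50": self.ap50,
                }
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def matches_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": m.image_id,
                    "gt_index": m.gt_index,
                    "det_index": m.det_index,
                    "iou": m.iou,
                    "confidence": m.confidence,
                }
                for m in self.matches
            ]
        )


def evaluate(
    gts: Sequence[BoxAnnotation], detections: Sequence, iou_thresh: float = 0.5
) -> EvalReport:
    """Fill the full report from per-image matching plus pooled AP50."""
    if not gts:
        raise ValueError("evaluate requires a non-empty ground-truth set")
    gt_by_image: dict[str, list[BoxAnnotation]] = {}
    for g in gts:
        gt_by_image.setdefault(g.image_id, []).append(g)
    det_by_image: dict[str, list] = {}
    for d in detections:
        det_by_image.setdefault(d.image_id, []).append(d)
    all_pairs: list[MatchedPair] = []
    for image_id in sorted(gt_by_image):
        all_pairs.extend(
            match_for_eval(gt_by_image[image_id], det_by_image.get(image_id, []))
        )
    ious = np.array([p.iou for p in all_pairs])
    confs = np.array([float(d.confidence) for d in detections])
    return EvalReport(
        n_images=len(gt_by_image),
        n_rois=len(gts),
        avg_iou=float(ious.mean()),
        avg_confidence=float(confs.mean()) if confs.size else 0.0,
        min_iou=float(ious.min()),
        min_confidence=float(confs.min()) if confs.size else 0.0,
        n_below_half_iou=int(np.sum(ious < iou_thresh)),
        ap50=ap50(gts, list(detections), iou_thresh=iou_thresh),
        matches=tuple(all_pairs),
    )
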