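"""Detection evaluation: IoU, NMS, precision/recall, AP/mAP, theoretical FPS.

Conventions: boxes are (x_min, y_min, x_max, y_max) in pixels, half-open;
matching is greedy by descending confidence with best-IoU tie-breaking and
each ground truth used at most once; AP uses 101-point interpolation of the
precision-recall curve (the COCO convention); mAP@50:95 averages AP over the
IoU grid 0.50:0.05:0.95; precision and recall are reported as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

IOU_GRID_50_95 = np.round(np.arange(0.5, 0.96, 0.05), 2)


@dataclass
class Detection:
    box: tuple          # (x_min, y_min, x_max, y_max), pixels
    class_id: int
    confidence: float
    image_id: int | str = 0

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class GroundTruth:
    box: tuple
    class_id: int
    image_id: int | str = 0


def iou(a, b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if not (ax1 < ax2 and ay1 < ay2 and bx1 < bx2 and by1 < by2):
        raise ValueError("degenerate box")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (n, 4) x (m, 4) -> (n, m)."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(0)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(dets: list[Detection], iou_threshold: float = 0.7) -> list[Detection]:
    """Greedy class-aware non-maximum suppression.

    Detections are visited by descending confidence (ties broken by earlier
    index); a detection is suppressed when a kept detection of the same
    class overlaps it with IoU strictly above the threshold.
    """
    if not dets:
        return []
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, i))
    kept: list[int] = []
    for i in order:
        suppressed = False
        for j in kept:
            if dets[j].class_id == dets[i].class_id and \
                    iou(dets[j].box, dets[i].box) > iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(i)
    return [dets[i] for i in sorted(kept)]


def _match(dets, truths, iou_cut):
    """Greedy per-image matching; returns a TP flag per detection.

    Detections sorted by confidence; each claims the unmatched same-class
    truth of highest IoU >= cut in its image.
    """
    flags = np.zeros(len(dets), dtype=bool)
    used: set[int] = set()
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, i))
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, iou_cut
        for j, t in enumerate(truths):
            if j in used or t.class_id != d.class_id \
                    or t.image_id != d.image_id:
                continue
            v = iou(d.box, t.box)
            if v >= best_iou and v > 0:
                if v > best_iou or best_j < 0:
                    best_j, best_iou = j, v
        if best_j >= 0:
            used.add(best_j)
            flags[i] = True
    return flags


@dataclass
class PRResult:
    tp: int
    fp: int
    fn: int
    precision: float        # percent
    recall: float           # percent
    precision_defined: bool = True


def pr_counts(dets: list[Detection], truths: list[GroundTruth],
              iou_cut: float = 0.5) -> PRResult:
    """TP/FP/FN and precision/recall (percent) at one IoU cut."""
    flags = _match(dets, truths, iou_cut)
    tp = int(flags.sum())
    fp = len(dets) - tp
    fn = len(truths) - tp
    if tp + fp == 0:
        return PRResult(tp, fp, fn, 0.0,
                        100.0 * tp / max(tp + fn, 1) if truths else 0.0,
                        precision_defined=False)
    p = 100.0 * tp / (tp + fp)
    r = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    return PRResult(tp, fp, fn, p, r)


@dataclass
class PRCurve:
    confidences: np.ndarray
    tp_flags: np.ndarray
    n_truths: int

    @property
    def precision(self):
        tp_cum = np.cumsum(self.tp_flags)
        fp_cum = np.cumsum(~self.tp_flags)
        return tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)

    @property
    def recall(self):
        if self.n_truths == 0:
            return np.zeros(len(self.tp_flags))
        return np.cumsum(self.tp_flags) / self.n_truths


def class_pr_curve(dets, truths, class_id, iou_cut=0.5) -> PRCurve:
    cls_dets = [d for d in dets if d.class_id == class_id]
    cls_truths = [t for t in truths if t.class_id == class_id]
    flags = _match(cls_dets, cls_truths, iou_cut)
    order = sorted(range(len(cls_dets)),
                   key=lambda i: (-cls_dets[i].confidence, i))
    conf = np.array([cls_dets[i].confidence for i in order], dtype=float)
    return PRCurve(conf, flags[order], len(cls_truths))


def average_precision(curve: PRCurve) -> float:
    """Area under the interpolated P(R) curve, 101-point convention."""
    if curve.n_truths == 0:
        return float("nan")
    if len(curve.tp_flags) == 0:
        return 0.0
    recall = curve.recall
    precision = curve.precision
    # monotone non-increasing precision envelope
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, grid, side="left")
    vals = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(vals.mean())


def map_score(per_class_ap: dict[int, float],
              iou_grid=None) -> float:
    """Unweighted mean of per-class AP, ignoring classes absent from truth."""
    if iou_grid is not None and len(iou_grid) == 0:
        raise ValueError("empty IoU grid")
    vals = [v for v in per_class_ap.values() if not np.isnan(v)]
    if not vals:
        raise ValueError("no class present in ground truth")
    return float(np.mean(vals))


def evaluate_detections(dets: list[Detection], truths: list[GroundTruth],
                        classes=None, iou_grid=None,
                        conf_for_pr: float = 0.25) -> dict:
    """Full metric report: per-class AP, mAP@50, mAP@50:95, P/R at 0.5.

    AP integrates over every detection; the single P/R operating point is
    taken at the deployment confidence threshold ``conf_for_pr``.
    """
    if classes is None:
        classes = sorted({t.class_id for t in truths})
    iou_grid = IOU_GRID_50_95 if iou_grid is None else np.asarray(iou_grid)
    if len(iou_grid) == 0:
        raise ValueError("empty IoU grid")
    ap50 = {c: average_precision(class_pr_curve(dets, truths, c, 0.5))
            for c in classes}
    ap_grid = {}
    for c in classes:
        aps = [average_precision(class_pr_curve(dets, truths, c, cut))
               for cut in iou_grid]
        ap_grid[c] = float(np.nanmean(aps)) if not all(np.isnan(aps)) \
            else float("nan")
    pr = pr_counts([d for d in dets if d.confidence >= conf_for_pr],
                   truths, 0.5)
    return {
        "ap50_per_class": ap50,
        "map50": map_score(ap50),
        "map50_95": map_score(ap_grid),
        "precision": pr.precision,
        "recall": pr.recall,
        "tp": pr.tp, "fp": pr.fp, "fn": pr.fn,
    }


def theoretical_fps(t_latency_ms: float) -> float:
    """Theoretical frame rate 1000 / latency, reported to 2 decimals."""
    if t_latency_ms <= 0:
        raise ValueError("latency must be positive")
    return round(1000.0 / t_latency_ms, 2)


def save_metrics_json(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
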