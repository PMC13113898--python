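"""Detection training loss: task-aligned assignment + CIoU + BCE + DFL.

The model family's composite objective: a task-aligned assigner picks, for
every ground-truth box, the top-k anchor cells (cell center inside the box)
ranked by ``score^alpha * IoU^beta``; assigned cells contribute a complete-
IoU box loss and a distribution-focal loss over the discretised box-side
distances, all cells contribute binary cross-entropy against the normalised
alignment scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad, cat
from .head import (make_anchors, flatten_predictions, decode_boxes,
                   dfl_expectation)
from .metrics import iou_matrix


@dataclass
class AssignResult:
    fg_mask: np.ndarray        # (A,) bool
    target_boxes: np.ndarray   # (A, 4) xyxy pixels
    target_scores: np.ndarray  # (A, nc) soft targets


def task_aligned_assign(scores, boxes, anchors, gt_boxes, gt_classes,
                        nc, topk=10, alpha=0.5, beta=6.0) -> AssignResult:
    """Single-image task-aligned assignment (all arrays detached numpy)."""
    A = anchors.shape[0]
    out = AssignResult(np.zeros(A, bool), np.zeros((A, 4), np.float32),
                       np.zeros((A, nc), np.float32))
    n = len(gt_classes)
    if n == 0:
        return out
    overlaps = iou_matrix(gt_boxes, boxes)                       # (n, A)
    cls_score = scores[:, gt_classes].T.clip(1e-9)               # (n, A)
    align = cls_score ** alpha * overlaps ** beta
    inside = ((anchors[None, :, 0] >= gt_boxes[:, 0:1])
              & (anchors[None, :, 0] < gt_boxes[:, 2:3])
              & (anchors[None, :, 1] >= gt_boxes[:, 1:2])
              & (anchors[None, :, 1] < gt_boxes[:, 3:4]))
    align = np.where(inside, align, 0.0)
    mask = np.zeros_like(align, dtype=bool)
    k = min(topk, A)
    top = np.argpartition(-align, k - 1, axis=1)[:, :k]
    for g in range(n):
        sel = top[g][align[g, top[g]] > 0]
        mask[g, sel] = True
    # anchors claimed by several gts go to the highest-overlap gt
    multi = mask.sum(axis=0) > 1
    if multi.any():
        best = overlaps.argmax(axis=0)
        for a in np.where(multi)[0]:
            mask[:, a] = False
            mask[best[a], a] = True
    fg = mask.any(axis=0)
    gt_idx = mask.argmax(axis=0)
    # normalise: per gt, peak target score equals its best overlap
    amax = (align * mask).max(axis=1, keepdims=True)
    omax = (overlaps * mask).max(axis=1, keepdims=True)
    norm = align * omax / (amax + 1e-9)
    for a in np.where(fg)[0]:
        g = gt_idx[a]
        out.fg_mask[a] = True
        out.target_boxes[a] = gt_boxes[g]
        out.target_scores[a, gt_classes[g]] = norm[g, a]
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    t = Tensor(targets.astype(np.float32))
    return logits.relu() - logits * t + (1.0 + (-logits.abs()).exp()).log()


def ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between (k,4) predicted and target xyxy boxes."""
    tx1, ty1 = Tensor(target[:, 0]), Tensor(target[:, 1])
    tx2, ty2 = Tensor(target[:, 2]), Tensor(target[:, 3])
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.relu() * ih.relu()
    area_p = (px2 - px1) * (py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter + 1e-7
    iou_v = inter / union
    # enclosing-box diagonal and center distance
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw ** 2 + ch ** 2 + 1e-7
    rho2 = ((px1 + px2 - tx1 - tx2) ** 2 + (py1 + py2 - ty1 - ty2) ** 2) * 0.25
    wp = (px2 - px1).clip(1e-7, 1e9)
    hp = (py2 - py1).clip(1e-7, 1e9)
    wt, ht = target[:, 2] - target[:, 0], target[:, 3] - target[:, 1]
    v = (Tensor(np.arctan(wt / (ht + 1e-7)).astype(np.float32))
         - (wp / hp).atan()) ** 2 * (4.0 / math.pi ** 2)
    with no_grad():
        alpha_d = v.data / (1.0 - iou_v.data + v.data + 1e-7)
    return iou_v - rho2 / c2 - v * Tensor(alpha_d)


class DetectionLoss:
    def __init__(self, nc=5, reg_max=16, strides=(8, 16, 32),
                 box_weight=7.5, cls_weight=0.5, dfl_weight=1.5,
                 topk=10, alpha=0.5, beta=6.0):
        self.nc, self.reg_max, self.strides = nc, reg_max, tuple(strides)
        self.box_w, self.cls_w, self.dfl_w = box_weight, cls_weight, dfl_weight
        self.topk, self.alpha, self.beta = topk, alpha, beta

    def __call__(self, raw_preds, targets) -> tuple[Tensor, dict]:
        """``targets``: per image, (classes (n,), boxes xyxy pixels (n,4))."""
        cls_logits, reg, shapes = flatten_predictions(raw_preds, self.reg_max)
        anchors, strides = make_anchors(shapes, self.strides)
        N, A, _ = cls_logits.shape
        with no_grad():
            scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data))
            boxes_np = decode_boxes(reg.detach(), anchors, strides,
                                    self.reg_max).data
        assigns = [task_aligned_assign(scores_np[i], boxes_np[i], anchors,
                                       np.asarray(t[1], np.float32).reshape(-1, 4),
                                       np.asarray(t[0], int), self.nc,
                                       self.topk, self.alpha, self.beta)
                   for i, t in enumerate(targets)]
        tscores = np.stack([a.target_scores for a in assigns])   # (N, A, nc)
        denom = max(float(tscores.sum()), 1.0)

        loss_cls = bce_with_logits(cls_logits, tscores).sum() * (1.0 / denom)

        fg = np.stack([a.fg_mask for a in assigns])
        n_fg = int(fg.sum())
        if n_fg:
            bidx, aidx = np.where(fg)
            tboxes = np.stack([a.target_boxes for a in assigns])[bidx, aidx]
            w = Tensor(tscores[bidx, aidx].sum(axis=1))
            pred_boxes = decode_boxes(reg, anchors, strides, self.reg_max)
            pb = pred_boxes[bidx, aidx]
            loss_box = ((1.0 - ciou(pb, tboxes)) * w).sum() * (1.0 / denom)
            # DFL over the discretised side distances, in stride units
            s = strides[aidx]
            d_t = np.stack([
                (anchors[aidx, 0] - tboxes[:, 0]) / s,
                (anchors[aidx, 1] - tboxes[:, 1]) / s,
                (tboxes[:, 2] - anchors[aidx, 0]) / s,
                (tboxes[:, 3] - anchors[aidx, 1]) / s], axis=1)
            d_t = d_t.clip(0, self.reg_max - 1 - 0.01)
            tl = np.floor(d_t).astype(int)
            wl, wr = tl + 1 - d_t, d_t - tl
            logits_fg = reg[bidx, aidx]                      # (k, 4, reg_max)
            logz = (logits_fg - logits_fg.max(axis=-1, keepdims=True))
            log_sm = logz - logz.exp().sum(axis=-1, keepdims=True).log()
            k = len(bidx)
            ii = np.repeat(np.arange(k), 4).reshape(k, 4)
            jj = np.tile(np.arange(4), k).reshape(k, 4)
            nll = -(log_sm[ii, jj, tl] * Tensor(wl.astype(np.float32))
                    + log_sm[ii, jj, np.minimum(tl + 1, self.reg_max - 1)]
                    * Tensor(wr.astype(np.float32)))
            loss_dfl = (nll.mean(axis=1) * w).sum() * (1.0 / denom)
        else:
            loss_box = Tensor(0.0)
            loss_dfl = Tensor(0.0)

        total = (loss_box * self.box_w + loss_cls * self.cls_w
                 + loss_dfl * self.dfl_w)
        parts = {"box": loss_box.item(), "cls": loss_cls.item(),
                 "dfl": loss_dfl.item(), "total": total.item()}
        return total, parts
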