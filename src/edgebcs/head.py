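"""Detection heads.

``EGDH`` is the efficient grouped detection head: per pyramid level a stem of
two stacked grouped 3x3 convolutions (group width fixed at 16 channels),
fused with the identity through a learnable scalar alpha, refined by one more
grouped 3x3 conv with BN, and mapped to class-logit and box-regression
tensors by two bias-carrying 1x1 convolutions without normalisation.  The
grouped layers cut FLOPs by exactly 1/g relative to dense convolutions:

    FLOPs_std = H * W * K^2 * C^2            (MACs, square conv)
    FLOPs_GC  = FLOPs_std / g,   g = C / 16

``DecoupledHead`` reconstructs the anchor-free baseline head of the family
the model is built on (separate regression and depthwise-separable
classification branches, distribution-focal box encoding with
``reg_max`` = 16 bins per side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, cat
from . import nn

GROUP_WIDTH = 16


def grouped_conv_flops(H: int, W: int, K: int, C: int, g: int) -> tuple[int, int]:
    """Multiply-accumulate counts for a dense vs grouped square conv layer.

    Returns ``(flops_std, flops_gc)`` with ``flops_std = H*W*K^2*C^2`` and
    ``flops_gc = flops_std / g``.
    """
    for name, v in (("H", H), ("W", W), ("K", K), ("C", C), ("g", g)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer")
    if C % g:
        raise ValueError(f"C={C} not divisible by g={g}")
    flops_std = H * W * K * K * C * C
    return flops_std, flops_std // g


@dataclass
class HeadConfig:
    channels: tuple          # per-level input channels
    nc: int = 5
    reg_max: int = 16
    group_width: int = GROUP_WIDTH
    strides: tuple = (8, 16, 32)


class EGDHLevel(nn.Module):
    def __init__(self, c: int, nc: int, reg_max: int,
                 group_width: int = GROUP_WIDTH):
        super().__init__()
        if c % group_width:
            # preceding 1x1 adapter enforces divisibility by the group width
            c_adj = ((c + group_width - 1) // group_width) * group_width
            self.adapter = nn.ConvBNAct(c, c_adj, 1)
            c = c_adj
        else:
            self.adapter = nn.Identity()
        g = c // group_width
        self.g = g
        self.stem = nn.Sequential(nn.ConvBNAct(c, c, 3, g=g),
                                  nn.ConvBNAct(c, c, 3, g=g))
        self.alpha = nn.Parameter(np.ones(1, dtype=np.float32))
        self.refine = nn.ConvBNAct(c, c, 3, g=g, act=None)
        # prediction convs: bias-enabled, deliberately unnormalised
        self.cls_pred = nn.Conv2d(c, nc, 1, bias=True)
        self.reg_pred = nn.Conv2d(c, 4 * reg_max, 1, bias=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x = self.adapter(x)
        fused = x * self.alpha.reshape(1, 1, 1, 1) + self.stem(x)
        r = self.refine(fused)
        return self.cls_pred(r), self.reg_pred(r)


class EGDH(nn.Module):
    """Efficient grouped detection head over the three pyramid levels."""

    def __init__(self, channels=(64, 64, 64), nc: int = 5, reg_max: int = 16,
                 group_width: int = GROUP_WIDTH, strides=(8, 16, 32)):
        super().__init__()
        self.cfg = HeadConfig(tuple(channels), nc, reg_max, group_width,
                              tuple(strides))
        self.nc, self.reg_max, self.strides = nc, reg_max, tuple(strides)
        self.levels = [EGDHLevel(c, nc, reg_max, group_width)
                       for c in channels]
        for lvl, s in zip(self.levels, self.strides):
            _init_pred_biases(lvl.cls_pred, lvl.reg_pred, nc, s)

    def forward(self, feats) -> list[tuple[Tensor, Tensor]]:
        return [lvl(f) for lvl, f in zip(self.levels, feats)]


class DecoupledHead(nn.Module):
    """Anchor-free decoupled baseline head (regression + DW-separable cls)."""

    def __init__(self, channels=(64, 128, 256), nc: int = 5, reg_max: int = 16,
                 strides=(8, 16, 32)):
        super().__init__()
        self.cfg = HeadConfig(tuple(channels), nc, reg_max, strides=tuple(strides))
        self.nc, self.reg_max, self.strides = nc, reg_max, tuple(strides)
        c2 = max(16, channels[0] // 4, reg_max * 4)
        c3 = max(channels[0], min(nc, 100))
        self.reg_branch = [
            nn.Sequential(nn.ConvBNAct(c, c2, 3), nn.ConvBNAct(c2, c2, 3),
                          nn.Conv2d(c2, 4 * reg_max, 1, bias=True))
            for c in channels]
        self.cls_branch = [
            nn.Sequential(
                nn.ConvBNAct(c, c, 3, g=c), nn.ConvBNAct(c, c3, 1),
                nn.ConvBNAct(c3, c3, 3, g=c3), nn.ConvBNAct(c3, c3, 1),
                nn.Conv2d(c3, nc, 1, bias=True))
            for c in channels]
        for cls_b, reg_b, s in zip(self.cls_branch, self.reg_branch,
                                   self.strides):
            _init_pred_biases(cls_b[-1], reg_b[-1], nc, s)

    def forward(self, feats) -> list[tuple[Tensor, Tensor]]:
        return [(cls(f), reg(f))
                for cls, reg, f in zip(self.cls_branch, self.reg_branch, feats)]


def _init_pred_biases(cls_conv, reg_conv, nc: int, stride: int,
                      imgsz: int = 640) -> None:
    """Prior-probability bias init for stable early training."""
    import math
    cls_conv.bias.data[:] = math.log(5 / nc / (imgsz / stride) ** 2)
    reg_conv.bias.data[:] = 1.0


def make_anchors(shapes, strides, offset: float = 0.5):
    """Cell-center anchor points in image pixels, concatenated over levels."""
    points, stride_list = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w) + offset) * s
        ys = (np.arange(h) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        points.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        stride_list.append(np.full(h * w, s))
    return (np.concatenate(points).astype(np.float32),
            np.concatenate(stride_list).astype(np.float32))


def dfl_expectation(reg: Tensor, reg_max: int) -> Tensor:
    """Distribution-focal decoding: softmax over bins -> expected distance.

    ``reg``: (N, A, 4, reg_max) logits; returns (N, A, 4) distances in
    stride units.
    """
    probs = reg.softmax(axis=-1)
    bins = Tensor(np.arange(reg_max, dtype=np.float32))
    return (probs * bins.reshape(1, 1, 1, reg_max)).sum(axis=-1)


def flatten_predictions(raw, reg_max: int):
    """Stack per-level (cls, reg) maps into (N, A, nc) and (N, A, 4, reg_max)."""
    cls_list, reg_list, shapes = [], [], []
    for cls_map, reg_map in raw:
        n, nc, h, w = cls_map.shape
        shapes.append((h, w))
        cls_list.append(cls_map.reshape(n, nc, h * w).transpose(0, 2, 1))
        reg_list.append(reg_map.reshape(n, 4 * reg_max, h * w)
                        .transpose(0, 2, 1).reshape(n, h * w, 4, reg_max))
    return cat(cls_list, axis=1), cat(reg_list, axis=1), shapes


def decode_boxes(reg: Tensor, anchors: np.ndarray, strides: np.ndarray,
                 reg_max: int) -> Tensor:
    """Distances (l, t, r, b) -> (x_min, y_min, x_max, y_max) in pixels."""
    d = dfl_expectation(reg, reg_max) * Tensor(strides.reshape(1, -1, 1))
    ax = Tensor(anchors[None, :, 0:1])
    ay = Tensor(anchors[None, :, 1:2])
    x1 = ax - d[:, :, 0:1]
    y1 = ay - d[:, :, 1:2]
    x2 = ax + d[:, :, 2:3]
    y2 = ay + d[:, :, 3:4]
    return cat([x1, y1, x2, y2], axis=2)
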