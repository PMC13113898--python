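"""Focal and global feature distillation (training-time only).

Transfers neck features from a large teacher detector to the lightweight
student.  The focal branch separates foreground from background with a
binary mask rasterized from the ground-truth boxes and a scale mask that
weights every foreground cell by the inverse area of its (smallest) box and
every background cell by the inverse background area; teacher-derived
spatial and channel attention maps (tempered softmax of mean absolute
activations) focus the squared feature difference, and an attention-transfer
term aligns the student's own attention with the teacher's.  The global
branch matches global-context-aggregated features through a shared context
block.  All parameters live outside the inference graph, so distillation
adds no deployment cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from . import nn


@dataclass
class DistillConfig:
    alpha_fg: float = 1.6e-3     # focal foreground weight
    beta_bg: float = 8.0e-4      # focal background weight
    gamma_at: float = 8.0e-4     # attention-transfer weight
    lambda_gl: float = 8.0e-6    # global-context weight
    temperature: float = 0.5

    def __post_init__(self):
        for name in ("alpha_fg", "beta_bg", "gamma_at", "lambda_gl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DistillMasks:
    binary: np.ndarray       # (H, W) in {0, 1}, 1 inside any gt box
    scale: np.ndarray        # (H, W) per-area weights
    spatial: np.ndarray      # (H, W), sums to H*W
    channel: np.ndarray      # (C,), sums to C
    temperature: float


def _attention_maps(feature: np.ndarray, T: float):
    """Spatial (H*W-sum) and channel (C-sum) tempered-softmax attentions."""
    C, H, W = feature.shape
    g_s = np.abs(feature).mean(axis=0)            # (H, W)
    e_s = np.exp((g_s - g_s.max()) / T)
    a_s = H * W * e_s / e_s.sum()
    g_c = np.abs(feature).mean(axis=(1, 2))       # (C,)
    e_c = np.exp((g_c - g_c.max()) / T)
    a_c = C * e_c / e_c.sum()
    return a_s, a_c


def build_focal_masks(boxes, feature_shape, teacher_feature, stride: float,
                      cfg: DistillConfig | None = None) -> DistillMasks:
    """Rasterize gt boxes into binary/scale masks and teacher attentions.

    ``boxes`` are (x_min, y_min, x_max, y_max) in image pixels;
    ``feature_shape`` is (C, H, W) at the given stride.  A feature cell is
    foreground when its center falls inside any box; foreground cells are
    weighted by the inverse area (in cells) of the smallest covering box,
    background cells by the inverse background area.
    """
    cfg = cfg or DistillConfig()
    C, H, W = feature_shape
    tf = np.asarray(teacher_feature, dtype=np.float64)
    if tf.shape != (C, H, W):
        raise ValueError("teacher feature does not match feature_shape")
    M = np.zeros((H, W), dtype=np.float64)
    S = np.zeros((H, W), dtype=np.float64)
    inv_area = np.full((H, W), np.inf)
    cy = (np.arange(H) + 0.5) * stride
    cx = (np.arange(W) + 0.5) * stride
    for (x1, y1, x2, y2) in boxes:
        inside = ((cy[:, None] >= y1) & (cy[:, None] < y2)
                  & (cx[None, :] >= x1) & (cx[None, :] < x2))
        n_cells = inside.sum()
        if n_cells == 0:
            continue
        M[inside] = 1.0
        inv_area[inside] = np.minimum(inv_area[inside], float(n_cells))
    fg = M > 0
    S[fg] = 1.0 / inv_area[fg]
    n_bg = int((~fg).sum())
    if n_bg:
        S[~fg] = 1.0 / n_bg
    a_s, a_c = _attention_maps(tf, cfg.temperature)
    return DistillMasks(M, S, a_s, a_c, cfg.temperature)


class GlobalContextBlock(nn.Module):
    """Context modeling + channel transform, shared by teacher and student."""

    def __init__(self, channels: int, reduction: int = 2):
        super().__init__()
        mid = max(1, channels // reduction)
        self.wk = nn.Conv2d(channels, 1, 1, bias=True)
        self.t1 = nn.Conv2d(channels, mid, 1, bias=True)
        self.t2 = nn.Conv2d(mid, channels, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        attn = self.wk(x).reshape(N, 1, H * W).softmax(axis=-1)
        flat = x.reshape(N, C, H * W)
        ctx = (flat * attn).sum(axis=-1).reshape(N, C, 1, 1)
        return x + self.t2(self.t1(ctx).relu())


class FGDLoss(nn.Module):
    """Focal+global distillation between one teacher/student feature pair.

    A trainable 1x1 adapter bridges a student-teacher channel mismatch;
    the global-context block is shared between both streams so the global
    term vanishes at teacher equality.
    """

    def __init__(self, student_channels: int, teacher_channels: int,
                 cfg: DistillConfig | None = None):
        super().__init__()
        self.cfg = cfg or DistillConfig()
        if student_channels != teacher_channels:
            self.adapter = nn.Conv2d(student_channels, teacher_channels, 1,
                                     bias=True)
        else:
            self.adapter = nn.Identity()
        self.gc = GlobalContextBlock(teacher_channels)

    def forward(self, f_t: Tensor, f_s: Tensor,
                masks: DistillMasks) -> tuple[Tensor, dict]:
        cfg = self.cfg
        f_s = self.adapter(_batched(f_s))
        f_t = _batched(f_t)
        if f_t.shape != f_s.shape:
            raise ValueError(
                f"teacher/student shape mismatch {f_t.shape} vs {f_s.shape} "
                "(adapter missing?)")
        N, C, H, W = f_t.shape
        M = Tensor(masks.binary[None, None])
        S = Tensor(masks.scale[None, None])
        AS = Tensor(masks.spatial[None, None])
        AC = Tensor(np.asarray(masks.channel, dtype=np.float32)
                    .reshape(1, C, 1, 1))
        diff2 = (f_t - f_s) ** 2 * AS * AC * S
        l_fg = (diff2 * M).sum() * cfg.alpha_fg
        l_bg = (diff2 * (1.0 - M)).sum() * cfg.beta_bg
        # attention transfer: student attentions vs teacher masks
        as_s, ac_s = _attention_tensors(f_s, cfg.temperature)
        l_at = ((as_s - AS.reshape(1, H, W)).abs().mean()
                + (ac_s - AC.reshape(1, C)).abs().mean()) * cfg.gamma_at
        # global context difference
        l_gl = ((self.gc(f_t) - self.gc(f_s)) ** 2).sum() * cfg.lambda_gl
        total = l_fg + l_bg + l_at + l_gl
        parts = {"focal_fg": l_fg.item(), "focal_bg": l_bg.item(),
                 "attention": l_at.item(), "global": l_gl.item()}
        return total, parts


def _batched(t: Tensor) -> Tensor:
    return t.reshape(1, *t.shape) if t.ndim == 3 else t


def _attention_tensors(f: Tensor, T: float):
    N, C, H, W = f.shape
    g_s = f.abs().mean(axis=1)                    # (N, H, W)
    a_s = (g_s * (1.0 / T)).reshape(N, H * W).softmax(axis=-1) * float(H * W)
    g_c = f.abs().mean(axis=(2, 3))               # (N, C)
    a_c = (g_c * (1.0 / T)).softmax(axis=-1) * float(C)
    return a_s.reshape(N, H, W), a_c


def fgd_loss(f_t, f_s, masks: DistillMasks, cfg: DistillConfig,
             module: FGDLoss | None = None):
    """Functional wrapper; builds a parameter module on the fly if needed."""
    if module is None:
        c_s = f_s.shape[-3]
        c_t = f_t.shape[-3]
        module = FGDLoss(c_s, c_t, cfg)
    return module(f_t, f_s, masks)
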