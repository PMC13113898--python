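"""Coordinate attention.

Pools the feature map separately along height and width (1-D global average
pooling), passes the concatenated directional descriptors through a shared
1x1 transform with BN and hard-swish, restores the channel dimension with
two independent 1x1 transforms, and reweights the input with the two
sigmoid gate vectors:

    y_c(i, j) = x_c(i, j) * g^h_c(i) * g^w_c(j)

The gates embed positional information into channel attention, which is what
lets the detector keep precise spatial localisation of small anatomical
regions (the tailhead) through the fusion stages.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autograd import Tensor, cat
from . import nn


@dataclass
class CAConfig:
    channels: int
    reduction: int = 32
    floor: int = 8

    @property
    def mid_channels(self) -> int:
        return max(self.floor, max(1, self.channels // self.reduction))


def directional_pool(x: Tensor) -> tuple[Tensor, Tensor]:
    """1-D global average pooling along each spatial direction.

    Returns ``z_h`` of shape (N, C, H) — the mean over the width of each
    row — and ``z_w`` of shape (N, C, W), the mean over the height of each
    column.
    """
    if x.ndim != 4:
        raise ValueError("expected NCHW input")
    if x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError("zero-sized spatial dimension")
    z_h = x.mean(axis=3)  # (N, C, H)
    z_w = x.mean(axis=2)  # (N, C, W)
    return z_h, z_w


class CoordAtt(nn.Module):
    """Coordinate attention block; preserves the input shape."""

    def __init__(self, channels: int, reduction: int = 32, floor: int = 8):
        super().__init__()
        self.cfg = CAConfig(channels, reduction, floor)
        mid = self.cfg.mid_channels
        # shared transform carries BN (hence no bias); the restoring
        # transforms carry a bias and no BN
        self.f1 = nn.Conv2d(channels, mid, 1, bias=False)
        self.bn = nn.BatchNorm2d(mid)
        self.f_h = nn.Conv2d(mid, channels, 1, bias=True)
        self.f_w = nn.Conv2d(mid, channels, 1, bias=True)

    def gates(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Directional gate vectors g_h (N,C,H,1) and g_w (N,C,1,W)."""
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        N, C, H, W = x.shape
        z_h, z_w = directional_pool(x)
        # concatenate along the pooled spatial axis, height part first
        z = cat([z_h.reshape(N, C, H, 1), z_w.reshape(N, C, W, 1)], axis=2)
        f = self.bn(self.f1(z)).hardswish()
        f_h, f_w = f[:, :, :H, :], f[:, :, H:, :]
        g_h = self.f_h(f_h).sigmoid()                       # (N, C, H, 1)
        g_w = self.f_w(f_w).sigmoid().transpose(0, 1, 3, 2)  # (N, C, 1, W)
        return g_h, g_w

    def forward(self, x: Tensor) -> Tensor:
        g_h, g_w = self.gates(x)
        return x * g_h * g_w
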