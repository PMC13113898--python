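"""Star-operation texture blocks.

The star block maps features through "large-kernel preprocessing — star
texture mapping — large-kernel post-refinement":

    X_pre  = DWConv_in^{7x7}(X)        (depthwise, with BN)
    X1     = W1 * X_pre + b1           (1x1 expansion branch)
    X2     = W2 * X_pre + b2           (1x1 expansion branch)
    Y_star = relu6(X1) (.) X2          (Hadamard product)
    Y_proj = W_out * Y_star            (1x1 projection back to C)
    Y      = DWConv_out^{7x7}(Y_proj) + X   (depthwise, deliberately no BN)

The elementwise product of two linear projections generates second-order
interaction terms x_i * x_j, an implicit high-dimensional feature map that
sharpens sensitivity to low-contrast fat texture; the asymmetric "BN before,
no BN after" normalisation keeps the refined high-frequency response
undistorted before the residual addition.

``TASM`` wraps star blocks in the split/merge skeleton of the C3k2 stage it
replaces: a 1x1 conv doubles the hidden width, the tensor is split in two,
one branch runs ``n`` sequential star blocks, and all intermediate outputs
are merged by a final 1x1 conv.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autograd import Tensor, cat
from . import nn


@dataclass
class StarBlockConfig:
    channels: int
    expansion: int = 2       # C' / C branch width ratio
    kernel: int = 7

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        if self.expansion < 1:
            raise ValueError("expansion must give C' >= C")


class StarBlock(nn.Module):
    def __init__(self, channels: int, expansion: int = 2):
        super().__init__()
        self.cfg = StarBlockConfig(channels, expansion)
        c, ce = channels, channels * expansion
        k = self.cfg.kernel
        self.dw_in = nn.Conv2d(c, c, k, g=c, bias=False)
        self.bn_in = nn.BatchNorm2d(c)
        self.f1 = nn.Conv2d(c, ce, 1, bias=True)
        self.f2 = nn.Conv2d(c, ce, 1, bias=True)
        self.w_out = nn.Conv2d(ce, c, 1, bias=True)
        self.dw_out = nn.Conv2d(c, c, k, g=c, bias=True)  # no BN after

    def star_core(self, x_pre: Tensor) -> Tensor:
        """relu6(W1 x + b1) (.) (W2 x + b2), the second-order feature map."""
        return self.f1(x_pre).relu6() * self.f2(x_pre)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        x_pre = self.bn_in(self.dw_in(x))
        y = self.dw_out(self.w_out(self.star_core(x_pre)))
        return y + x


@dataclass
class TasmConfig:
    in_channels: int
    out_channels: int
    n: int = 1
    hidden_ratio: float = 0.5
    expansion: int = 2

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one star bottleneck unit")


class TASM(nn.Module):
    """Texture-aware star module: C3k2-topology stage with star bottlenecks."""

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5,
                 expansion: int = 2):
        super().__init__()
        self.cfg = TasmConfig(c1, c2, n, e, expansion)
        c = int(c2 * e)
        self.c = c
        self.cv1 = nn.ConvBNAct(c1, 2 * c, 1)
        self.cv2 = nn.ConvBNAct((2 + n) * c, c2, 1)
        self.m = [StarBlock(c, expansion) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a, b = y[:, :self.c], y[:, self.c:]
        outs = [a, b]
        for block in self.m:
            outs.append(block(outs[-1]))
        return self.cv2(cat(outs, axis=1))
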