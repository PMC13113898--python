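"""Position-sensitive feature fusion (PSFF) neck.

A PAN-style top-down then bottom-up pass over the three backbone levels in
which every fusion node replaces channel concatenation with a gated
multiplicative-additive merge at one constant channel width:

    F = CA(L) (.) sigmoid(Conv1x1(U)) + U

where ``L`` is the lateral (skip) stream calibrated by coordinate attention
and ``U`` is the resampled incoming stream — learned stride-2 transposed
convolution on the way down, stride-2 3x3 convolution on the way up.  The
deep stream acts as the gating signal, suppressing background activations
while channel counts stay constant through every node.  Each fusion node is
followed by a bottleneck stage (C3k2 in the intermediate ablation variant,
TASM in the full model).

The baseline concatenation neck of the donor family is kept behind
``BaselineNeck`` for ablation parity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autograd import Tensor
from . import nn
from .attention import CoordAtt
from .blocks import C3k2, Concat
from .star import TASM


@dataclass
class FusionNodeConfig:
    channels: int
    resample: str  # "up" (transposed conv) | "down" (strided conv)


class GatedFusion(nn.Module):
    """One PSFF node: CA-calibrated lateral gated by the resampled stream."""

    def __init__(self, channels: int):
        super().__init__()
        self.cfg = FusionNodeConfig(channels, resample="-")
        self.ca = CoordAtt(channels)
        self.gate = nn.Conv2d(channels, channels, 1, bias=True)

    def forward(self, lateral: Tensor, incoming: Tensor) -> Tensor:
        if lateral.shape[2:] != incoming.shape[2:]:
            raise ValueError(
                f"spatial mismatch {lateral.shape[2:]} vs {incoming.shape[2:]}")
        if lateral.shape[1] != incoming.shape[1]:
            raise ValueError("constant-channel contract violated")
        return self.ca(lateral) * self.gate(incoming).sigmoid() + incoming


def _stage(kind: str, c: int, expansion: int):
    if kind == "tasm":
        return TASM(c, c, n=1, expansion=expansion)
    return C3k2(c, c, n=1, c3k=False)


class PSFFNeck(nn.Module):
    """Gated-fusion neck at one constant width over strides 8/16/32."""

    def __init__(self, in_channels=(64, 128, 256), width: int = 64,
                 stage: str = "c3k2", star_expansion: int = 2):
        super().__init__()
        if len(in_channels) != 3:
            raise ValueError("neck expects exactly three pyramid levels")
        c3, c4, c5 = in_channels
        w = self.width = width
        # lateral projections to the constant width
        self.lat3 = nn.ConvBNAct(c3, w, 1)
        self.lat4 = nn.ConvBNAct(c4, w, 1)
        self.lat5 = nn.ConvBNAct(c5, w, 1)
        # top-down: learned upsampling of the deep stream
        self.up4 = nn.ConvTransposeBNAct(c5, w, 2, 2)
        self.fuse4 = GatedFusion(w)
        self.stage4 = _stage(stage, w, star_expansion)
        self.up3 = nn.ConvTransposeBNAct(w, w, 2, 2)
        self.fuse3 = GatedFusion(w)
        self.stage3 = _stage(stage, w, star_expansion)
        # bottom-up: strided-conv downsampling of the shallow stream
        self.down4 = nn.ConvBNAct(w, w, 3, 2)
        self.fuse4b = GatedFusion(w)
        self.stage4b = _stage(stage, w, star_expansion)
        self.down5 = nn.ConvBNAct(w, w, 3, 2)
        self.fuse5b = GatedFusion(w)
        self.stage5b = _stage(stage, w, star_expansion)

    @property
    def out_channels(self):
        return (self.width, self.width, self.width)

    def upsample_learned(self, which: str, x: Tensor) -> Tensor:
        """Stride-2 transposed-convolution upsampling (exposed for tests)."""
        return {"p4": self.up4, "p3": self.up3}[which](x)

    def forward(self, feats):
        if len(feats) != 3:
            raise ValueError("expected features at strides 8/16/32")
        p3, p4, p5 = feats
        # top-down
        u4 = self.up4(p5)
        t4 = self.stage4(self.fuse4(self.lat4(p4), u4))
        u3 = self.up3(t4)
        n3 = self.stage3(self.fuse3(self.lat3(p3), u3))
        # bottom-up
        d4 = self.down4(n3)
        n4 = self.stage4b(self.fuse4b(t4, d4))
        d5 = self.down5(n4)
        n5 = self.stage5b(self.fuse5b(self.lat5(p5), d5))
        return [n3, n4, n5]


class BaselineNeck(nn.Module):
    """Concatenation PAN neck of the nano baseline (nearest upsampling)."""

    def __init__(self, in_channels=(128, 128, 256), out_channels=(64, 128, 256),
                 c3k_last=True, n=1):
        super().__init__()
        b3, b4, b5 = in_channels
        o3, o4, o5 = out_channels
        self.up = nn.UpsampleNearest2()
        self.cat = Concat()
        self.stage4 = C3k2(b5 + b4, o4, n=n, c3k=False)
        self.stage3 = C3k2(o4 + b3, o3, n=n, c3k=False)
        self.down4 = nn.ConvBNAct(o3, o3, 3, 2)
        self.stage4b = C3k2(o3 + o4, o4, n=n, c3k=False)
        self.down5 = nn.ConvBNAct(o4, o4, 3, 2)
        self.stage5b = C3k2(o4 + b5, o5, n=n, c3k=c3k_last)
        self.out_channels = (o3, o4, o5)

    def forward(self, feats):
        p3, p4, p5 = feats
        t4 = self.stage4(self.cat([self.up(p5), p4]))
        n3 = self.stage3(self.cat([self.up(t4), p3]))
        n4 = self.stage4b(self.cat([self.down4(n3), t4]))
        n5 = self.stage5b(self.cat([self.down5(n4), p5]))
        return [n3, n4, n5]
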