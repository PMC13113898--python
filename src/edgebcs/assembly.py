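"""Model assembly, complexity accounting and checkpoints.

Builds the nano-scale baseline detector and its ablation ladder:

* ``baseline``   — public nano topology: C3k2 backbone, SPPF, C2PSA,
  concatenation PAN neck, decoupled head.
* ``psff``       — gated-fusion neck (PSFF) at one constant width.
* ``psff-tasm``  — plus star-operation bottlenecks (TASM) in backbone and
  neck stages.
* ``full``       — plus the efficient grouped detection head (EGDH).

Complexity is counted on the conv-BN-fused inference graph: one
multiply-accumulate = 2 FLOPs, summed over all conv/matmul kernels at the
given input size.  Serialized size assumes every learnable parameter and BN
running statistic stored at 16-bit floating precision.
"""

from __future__ import annotations

import copy

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, Profile, no_grad
from . import nn
from .blocks import C3k2, SPPF, C2PSA
from .star import TASM
from .neck import PSFFNeck, BaselineNeck
from .head import EGDH, DecoupledHead

# depth multiplier, width multiplier, max channels
SCALES = {
    "n": (0.50, 0.25, 1024),
    "s": (0.50, 0.50, 1024),
    "l": (1.00, 1.00, 512),
    "t": (0.50, 0.125, 1024),   # tiny width for desk-scale experiments
}

VARIANTS = ("baseline", "psff", "psff-tasm", "full")


def _make_divisible(x: float, d: int = 8) -> int:
    return max(d, int(round(x / d) * d))


@dataclass
class ModelConfig:
    variant: str = "full"
    scale: str = "n"
    nc: int = 5
    imgsz: int = 640
    reg_max: int = 16
    neck_width: int | None = None      # PSFF constant width; default: 256*w
    # C'/C of the star branches per backbone stage (P2, P3, P4, P5) and for
    # the neck stages: wide texture mapping where spatial detail lives,
    # narrow where channels are many
    star_expansion: tuple | int = (4, 4, 2, 1, 4)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    def to_dict(self):
        return asdict(self)


class Backbone(nn.Module):
    """Nano-family backbone; stages are C3k2 or TASM per variant."""

    def __init__(self, scale: str = "n", tasm: bool = False,
                 star_expansion=(4, 4, 2, 1)):
        super().__init__()
        depth, width, maxch = SCALES[scale]
        chs = [_make_divisible(min(c, maxch) * width)
               for c in (64, 128, 256, 512, 1024)]
        n = max(round(2 * depth), 1)
        c3k = [False, False, True, True] if scale not in "mlx" else [True] * 4
        if isinstance(star_expansion, int):
            star_expansion = (star_expansion,) * 4

        def stage(c1, c2, flag, exp, e=0.5):
            if tasm:
                return TASM(c1, c2, n=n, e=e, expansion=exp)
            return C3k2(c1, c2, n=n, c3k=flag, e=e)

        self.l0 = nn.ConvBNAct(3, chs[0], 3, 2)
        self.l1 = nn.ConvBNAct(chs[0], chs[1], 3, 2)
        self.l2 = stage(chs[1], chs[2], c3k[0], star_expansion[0], e=0.25)
        self.l3 = nn.ConvBNAct(chs[2], chs[2], 3, 2)
        self.l4 = stage(chs[2], chs[3], c3k[1], star_expansion[1], e=0.25)
        self.l5 = nn.ConvBNAct(chs[3], chs[3], 3, 2)
        self.l6 = stage(chs[3], chs[3], c3k[2], star_expansion[2])
        self.l7 = nn.ConvBNAct(chs[3], chs[4], 3, 2)
        self.l8 = stage(chs[4], chs[4], c3k[3], star_expansion[3])
        self.l9 = SPPF(chs[4], chs[4])
        self.l10 = C2PSA(chs[4], chs[4], n=n)
        self.out_channels = (chs[3], chs[3], chs[4])   # strides 8, 16, 32
        self.neck_out = (chs[2], chs[3], chs[4])       # baseline neck widths

    def forward(self, x):
        x = self.l1(self.l0(x))
        x = self.l3(self.l2(x))
        p3 = self.l4(x)
        p4 = self.l6(self.l5(p3))
        p5 = self.l10(self.l9(self.l8(self.l7(p4))))
        return [p3, p4, p5]


class Detector(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        nn.set_seed(cfg.seed)
        tasm = cfg.variant in ("psff-tasm", "full")
        exp = cfg.star_expansion
        if isinstance(exp, int):
            exp = (exp,) * 5
        self.backbone = Backbone(cfg.scale, tasm=tasm,
                                 star_expansion=tuple(exp[:4]))
        b3, b4, b5 = self.backbone.out_channels
        if cfg.variant == "baseline":
            self.neck = BaselineNeck((b3, b4, b5), self.backbone.neck_out)
        else:
            _, width, _ = SCALES[cfg.scale]
            w = cfg.neck_width or _make_divisible(256 * width)
            self.neck = PSFFNeck((b3, b4, b5), width=w,
                                 stage="tasm" if tasm else "c3k2",
                                 star_expansion=exp[-1])
        head_ch = self.neck.out_channels
        if cfg.variant == "full":
            self.head = EGDH(head_ch, nc=cfg.nc, reg_max=cfg.reg_max)
        else:
            self.head = DecoupledHead(head_ch, nc=cfg.nc, reg_max=cfg.reg_max)

    @property
    def strides(self):
        return self.head.strides

    def forward_features(self, x: Tensor):
        return self.neck(self.backbone(x))

    def forward(self, x: Tensor):
        return self.head(self.forward_features(x))


def build_model(cfg: ModelConfig) -> Detector:
    return Detector(cfg)


@dataclass
class ComplexityReport:
    variant: str
    params: int
    gflops: float
    fp16_size_mb: float
    macs: int = 0
    elementwise: int = 0

    def __str__(self):
        return (f"{self.variant}: {self.params:,} params, "
                f"{self.gflops:.1f} GFLOPs, {self.fp16_size_mb:.1f} MB (fp16)")


def complexity_report(model: Detector, imgsz: int | None = None,
                      fuse: bool = True) -> ComplexityReport:
    """Layerwise FLOP/parameter accounting on the fused inference graph."""
    imgsz = imgsz or model.cfg.imgsz
    params = model.num_parameters()
    size_mb = checkpoint_size(model)
    probe = copy.deepcopy(model).eval()
    if fuse:
        probe.fuse()
    x = Tensor(np.zeros((1, 3, imgsz, imgsz), dtype=np.float32))
    with no_grad(), Profile() as prof:
        probe(x)
    return ComplexityReport(model.cfg.variant, params,
                            gflops=2 * prof.macs / 1e9,
                            fp16_size_mb=size_mb,
                            macs=prof.macs, elementwise=prof.elementwise)


def checkpoint_size(model: nn.Module) -> float:
    """Serialized model size in MB: fp16 params plus BN running statistics."""
    n = model.num_parameters() + model.num_buffer_elems()
    return round(2 * n / 1e6, 1)


def save_checkpoint(model: Detector, path) -> None:
    """Flat key->tensor container at FP16, with the model config embedded."""
    arrays = {f"w::{k}": v.astype(np.float16)
              for k, v in model.state_dict().items()}
    arrays["config"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        cfg = ModelConfig(**json.loads(bytes(z["config"]).decode()))
        model = build_model(cfg)
        state = {k[3:]: z[k].astype(np.float32)
                 for k in z.files if k.startswith("w::")}
    model.load_state_dict(state)
    return model
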