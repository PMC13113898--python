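"""Backbone/neck building blocks of the YOLO11 family baseline.

Faithful reconstructions of the public nano-scale topology: bottlenecks,
C3k/C3k2 stages, SPPF pooling, the C2PSA attention stage and the channel
concatenation node used by the baseline neck.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, cat
from . import nn


class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, k=(3, 3), e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = nn.ConvBNAct(c1, c_, k[0])
        self.cv2 = nn.ConvBNAct(c_, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(nn.Module):
    def __init__(self, c1, c2, n=2, shortcut=True, e=0.5, k=3):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = nn.ConvBNAct(c1, c_, 1)
        self.cv2 = nn.ConvBNAct(c1, c_, 1)
        self.cv3 = nn.ConvBNAct(2 * c_, c2, 1)
        self.m = [Bottleneck(c_, c_, shortcut, k=(k, k), e=1.0)
                  for _ in range(n)]

    def forward(self, x):
        a = self.cv1(x)
        for blk in self.m:
            a = blk(a)
        return self.cv3(cat([a, self.cv2(x)], axis=1))


class C3k2(nn.Module):
    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True):
        super().__init__()
        c = int(c2 * e)
        self.c = c
        self.cv1 = nn.ConvBNAct(c1, 2 * c, 1)
        self.cv2 = nn.ConvBNAct((2 + n) * c, c2, 1)
        self.m = [C3k(c, c, 2, shortcut) if c3k
                  else Bottleneck(c, c, shortcut, k=(3, 3), e=0.5)
                  for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        outs = [y[:, :self.c], y[:, self.c:]]
        for blk in self.m:
            outs.append(blk(outs[-1]))
        return self.cv2(cat(outs, axis=1))


class SPPF(nn.Module):
    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = nn.ConvBNAct(c1, c_, 1)
        self.cv2 = nn.ConvBNAct(4 * c_, c2, 1)
        self.pool = nn.MaxPool2d(k, 1)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(cat(y, axis=1))


class Attention(nn.Module):
    def __init__(self, dim, num_heads, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = nn.ConvBNAct(dim, h, 1, act=None)
        self.proj = nn.ConvBNAct(dim, dim, 1, act=None)
        self.pe = nn.ConvBNAct(dim, dim, 3, g=dim, act=None)

    def forward(self, x):
        N, C, H, W = x.shape
        L = H * W
        qkv = self.qkv(x).reshape(N, self.num_heads,
                                  self.key_dim * 2 + self.head_dim, L)
        q = qkv[:, :, :self.key_dim]
        k = qkv[:, :, self.key_dim:self.key_dim * 2]
        v = qkv[:, :, self.key_dim * 2:]
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = v @ attn.transpose(0, 1, 3, 2)
        out = out.reshape(N, C, H, W) + self.pe(v.reshape(N, C, H, W))
        return self.proj(out)


class PSABlock(nn.Module):
    def __init__(self, c, num_heads):
        super().__init__()
        self.attn = Attention(c, num_heads)
        self.ffn = nn.Sequential(nn.ConvBNAct(c, c * 2, 1),
                                 nn.ConvBNAct(c * 2, c, 1, act=None))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(nn.Module):
    def __init__(self, c1, c2, n=1, e=0.5):
        super().__init__()
        c = int(c1 * e)
        self.c = c
        self.cv1 = nn.ConvBNAct(c1, 2 * c, 1)
        self.cv2 = nn.ConvBNAct(2 * c, c1, 1)
        self.m = [PSABlock(c, max(1, c // 64)) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, :self.c], y[:, self.c:]
        for blk in self.m:
            b = blk(b)
        return self.cv2(cat([a, b], axis=1))


class Concat(nn.Module):
    """Channel concatenation fusion node (baseline neck only)."""

    def forward(self, xs):
        return cat(xs, axis=1)
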