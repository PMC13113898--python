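"""Neural-network layer library on top of :mod:`edgebcs.autograd`.

Implements the layer vocabulary of the YOLO11 family — convolution with
batch normalisation and SiLU, depthwise and grouped convolution, transposed
convolution, max-pooling — plus lossless conv-BN fusion for the inference
graph.  Modules follow the familiar ``parameters() / train() / eval() /
state_dict()`` protocol.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

_rng = np.random.default_rng(0)


def set_seed(seed: int) -> None:
    """Reseed the global parameter-initialisation RNG."""
    global _rng
    _rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    # -- state ----------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def num_buffer_elems(self) -> int:
        return sum(b.size for _, b in self.named_buffers())

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            v = np.asarray(v, dtype=np.float32)
            if k in own:
                if own[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                own[k].data[...] = v
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unexpected key {k}")

    def fuse(self):
        """Recursively fold BN layers into preceding convolutions."""
        for m in self.modules():
            if isinstance(m, (ConvBNAct, ConvTransposeBNAct)) and m.bn is not None:
                _fuse_into(m)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __getitem__(self, i):
        return self.layers[i]

    def __len__(self):
        return len(self.layers)


class Identity(Module):
    def forward(self, x):
        return x


# -- activations ---------------------------------------------------------------
class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class Hardswish(Module):
    def forward(self, x):
        return x.hardswish()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


# -- core layers ---------------------------------------------------------------
def _kaiming(shape, fan_in):
    bound = math.sqrt(1.0 / fan_in)
    return _rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Bare convolution (optionally grouped), NCHW."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, bias=True):
        super().__init__()
        if c1 % g or c2 % g:
            raise ValueError(f"channels ({c1}->{c2}) not divisible by groups {g}")
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = k // 2 if p is None else p
        fan_in = c1 // g * k * k
        self.weight = Parameter(_kaiming((c2, c1 // g, k, k), fan_in))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, stride=self.s,
                        padding=self.p, groups=self.g)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (
                var.data.ravel() - self.running_var)
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        g = self.gamma.reshape(1, self.c, 1, 1)
        b = self.beta.reshape(1, self.c, 1, 1)
        return xhat * g + b


def fuse_conv_bn(conv: Conv2d, bn: BatchNorm2d) -> Conv2d:
    """Fold frozen BN statistics into the convolution (inference only).

    Returns a new convolution whose output matches ``bn(conv(x))`` for any
    input; works groupwise for grouped convolutions since the scaling is
    per output channel.
    """
    scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
    fused = Conv2d(conv.c1, conv.c2, conv.k, conv.s, conv.p, conv.g, bias=True)
    fused.weight.data[...] = conv.weight.data * scale[:, None, None, None]
    b0 = conv.bias.data if conv.bias is not None else 0.0
    fused.bias.data[...] = bn.beta.data + (b0 - bn.running_mean) * scale
    return fused


class ConvBNAct(Module):
    """Convolution + BatchNorm + activation (the family's `Conv` block)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act="silu"):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = _make_act(act)

    def forward(self, x):
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return self.act(y)


class ConvTranspose2d(Module):
    def __init__(self, c1, c2, k=2, s=2, p=0, bias=True):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.p = c1, c2, k, s, p
        fan_in = c1 * k * k
        self.weight = Parameter(_kaiming((c1, c2, k, k), fan_in))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        return x.conv_transpose2d(self.weight, self.bias,
                                  stride=self.s, padding=self.p)


class ConvTransposeBNAct(Module):
    """Learned stride-2 upsampling: transposed conv + BN + SiLU."""

    def __init__(self, c1, c2, k=2, s=2, act="silu"):
        super().__init__()
        self.conv = ConvTranspose2d(c1, c2, k, s, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = _make_act(act)

    def forward(self, x):
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return self.act(y)


class MaxPool2d(Module):
    def __init__(self, k, s=1, p=None):
        super().__init__()
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p

    def forward(self, x):
        return x.maxpool2d(self.k, self.s, self.p)


class UpsampleNearest2(Module):
    def forward(self, x):
        return x.upsample_nearest2()


def _make_act(act):
    if act in (None, "none", False):
        return Identity()
    return {"silu": SiLU, "relu6": ReLU6, "hardswish": Hardswish,
            "sigmoid": Sigmoid}[act]()


def _fuse_into(m) -> None:
    conv = m.conv
    bn = m.bn
    if isinstance(conv, Conv2d):
        m.conv = fuse_conv_bn(conv, bn)
    else:  # transposed: scaling acts on the Cout axis (axis 1 of the weight)
        scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
        fused = ConvTranspose2d(conv.c1, conv.c2, conv.k, conv.s, conv.p,
                                bias=True)
        fused.weight.data[...] = conv.weight.data * scale[None, :, None, None]
        b0 = conv.bias.data if conv.bias is not None else 0.0
        fused.bias.data[...] = bn.beta.data + (b0 - bn.running_mean) * scale
        m.conv = fused
    m.bn = None
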