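"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the detector needs: broadcasted
arithmetic, matmul, 2-D (grouped) convolution and transposed convolution via
im2col/col2im, max-pooling, nearest upsampling, reductions, reshapes and the
activation functions of the model family.  Gradients are accumulated by
closure-based backward functions in reverse topological order.

A global profiling context lets the convolution/matmul primitives report
multiply-accumulate counts and elementwise primitives report element counts;
the complexity profiler in :mod:`edgebcs.assembly` builds on this.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "Profile", "cat", "stack"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


_profile_stack: list["Profile"] = []


class Profile:
    """Collects MAC and elementwise-op counts from the primitives.

    ``macs`` counts multiply-accumulates of conv/matmul kernels; ``elementwise``
    counts output elements of arithmetic primitives (one op per element).
    """

    def __init__(self):
        self.macs = 0
        self.elementwise = 0

    def __enter__(self):
        _profile_stack.append(self)
        return self

    def __exit__(self, *exc):
        _profile_stack.pop()
        return False


def _log_macs(n: int) -> None:
    for p in _profile_stack:
        p.macs += int(n)


def _log_elem(n: int) -> None:
    for p in _profile_stack:
        p.elementwise += int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        _log_elem(out_data.size)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        _log_elem(out_data.size)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data
        _log_elem(out_data.size)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / (other.data ** 2),
                                      other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data
        _log_macs(out_data.size * self.data.shape[-1])

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- pointwise functions --------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def relu6(self):
        out_data = np.clip(self.data, 0.0, 6.0)
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * ((self.data > 0) & (self.data < 6)))

        return self._make(out_data, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return self._make(out_data, (self,), backward)

    def hardswish(self):
        # x * relu6(x + 3) / 6
        inner = np.clip(self.data + 3.0, 0.0, 6.0)
        out_data = self.data * inner / 6.0
        _log_elem(out_data.size)

        def backward(g):
            d = np.where(self.data <= -3.0, 0.0,
                         np.where(self.data >= 3.0, 1.0,
                                  (2.0 * self.data + 3.0) / 6.0))
            self._accum(g * d)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accum(g * ((self.data >= lo) & (self.data <= hi)))

        return self._make(out_data, (self,), backward)

    def atan(self):
        out_data = np.arctan(self.data)
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g / (1.0 + self.data ** 2))

        return self._make(out_data, (self,), backward)

    def minimum(self, other):
        other = _as_tensor(other)
        out_data = np.minimum(self.data, other.data)
        _log_elem(out_data.size)

        def backward(g):
            a_is_min = self.data <= other.data
            self._accum(_unbroadcast(g * a_is_min, self.data.shape))
            other._accum(_unbroadcast(g * ~a_is_min, other.data.shape))

        return self._make(out_data, (self, other), backward)

    def maximum(self, other):
        other = _as_tensor(other)
        out_data = np.maximum(self.data, other.data)
        _log_elem(out_data.size)

        def backward(g):
            a_is_max = self.data >= other.data
            self._accum(_unbroadcast(g * a_is_max, self.data.shape))
            other._accum(_unbroadcast(g * ~a_is_max, other.data.shape))

        return self._make(out_data, (self, other), backward)

    def abs(self):
        out_data = np.abs(self.data)
        _log_elem(out_data.size)

        def backward(g):
            self._accum(g * np.sign(self.data))

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            expanded = out_data if keepdims or axis is None else (
                np.expand_dims(out_data, axis))
            mask = (self.data == expanded)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape

        def backward(g):
            self._accum(g.reshape(src_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def pad2d(self, pad: int):
        """Zero padding on the two trailing (spatial) axes."""
        if pad == 0:
            return self
        pw = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, pw)

        def backward(g):
            sl = tuple([slice(None)] * (self.ndim - 2)
                       + [slice(pad, -pad), slice(pad, -pad)])
            self._accum(g[sl])

        return self._make(out_data, (self,), backward)

    # -- convolution primitives ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1):
        """2-D convolution, NCHW, weight (Cout, Cin/g, kh, kw)."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        Cout, Cin_g, kh, kw = w.shape
        if C % groups or Cout % groups or C // groups != Cin_g:
            raise ValueError(
                f"channel/group mismatch: input {C}, groups {groups}, "
                f"weight expects {Cin_g} per group")
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding),
                           (padding, padding)))
        Ho = (x.shape[2] - kh) // stride + 1
        Wo = (x.shape[3] - kw) // stride + 1
        if Ho < 1 or Wo < 1:
            raise ValueError("spatial dims collapse to zero")
        cols = _im2col(x, kh, kw, stride, Ho, Wo)          # (N, C*kh*kw, L)
        L = Ho * Wo
        g = groups
        cols_g = cols.reshape(N, g, Cin_g * kh * kw, L)
        w_g = w.reshape(g, Cout // g, Cin_g * kh * kw)
        out = np.matmul(w_g[None], cols_g)                 # (N, g, Cout/g, L)
        out_data = out.reshape(N, Cout, Ho, Wo)
        _log_macs(N * Cout * Ho * Wo * Cin_g * kh * kw)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, Cout, 1, 1)

        self_t, weight_t, bias_t = self, weight, bias
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(gout):
            gout4 = gout.reshape(N, g, Cout // g, L)
            # grad wrt weight
            if weight_t.requires_grad:
                gw = np.matmul(gout4, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
                weight_t._accum(gw.reshape(w.shape))
            if bias_t is not None and bias_t.requires_grad:
                bias_t._accum(gout.sum(axis=(0, 2, 3)))
            if self_t.requires_grad:
                gcols = np.matmul(w_g.transpose(0, 2, 1)[None], gout4)
                gcols = gcols.reshape(N, C * kh * kw, L)
                gx = _col2im(gcols, x.shape, kh, kw, stride, Ho, Wo)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self_t._accum(gx)

        return self._make(out_data, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2, padding: int = 0):
        """Transposed convolution, weight (Cin, Cout, kh, kw).

        Equivalent to zero-stuffing the input by ``stride`` then running an
        ordinary convolution with the spatially flipped kernel.
        """
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        Cin_w, Cout, kh, kw = w.shape
        if C != Cin_w:
            raise ValueError(f"channel mismatch: input {C} vs weight {Cin_w}")
        Ho = (H - 1) * stride - 2 * padding + kh
        Wo = (W - 1) * stride - 2 * padding + kw
        # scatter approach: accumulate x (.) w into the output grid
        out_data = np.zeros((N, Cout, Ho + 2 * padding, Wo + 2 * padding),
                            dtype=np.float32)
        # (N,C,H,W) x (C,Cout,kh,kw) -> (N,Cout,H,W,kh,kw)
        prod = np.einsum("nchw,cokl->nohwkl", x, w)
        _log_macs(N * C * Cout * H * W * kh * kw)
        for i in range(kh):
            for j in range(kw):
                out_data[:, :, i:i + H * stride:stride,
                         j:j + W * stride:stride] += prod[:, :, :, :, i, j]
        if padding:
            out_data = out_data[:, :, padding:-padding, padding:-padding]
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, Cout, 1, 1)

        self_t, weight_t, bias_t = self, weight, bias
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(gout):
            if padding:
                gout_p = np.pad(gout, ((0, 0), (0, 0), (padding, padding),
                                       (padding, padding)))
            else:
                gout_p = gout
            # grad wrt x: ordinary strided correlation of gout with w
            windows = np.lib.stride_tricks.sliding_window_view(
                gout_p, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
            # windows: (N, Cout, H, W, kh, kw)
            if self_t.requires_grad:
                gx = np.einsum("nohwkl,cokl->nchw", windows, w)
                self_t._accum(gx.astype(np.float32))
            if weight_t.requires_grad:
                gw = np.einsum("nohwkl,nchw->cokl", windows, x)
                weight_t._accum(gw.astype(np.float32))
            if bias_t is not None and bias_t.requires_grad:
                bias_t._accum(gout.sum(axis=(0, 2, 3)))

        return self._make(out_data, parents, backward)

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0):
        x = self.data
        N, C, H, W = x.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding),
                           (padding, padding)),
                       constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(
            x, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
        Ho, Wo = win.shape[2], win.shape[3]
        flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        xpad_shape = x.shape

        def backward(g):
            gx = np.zeros(xpad_shape, dtype=np.float32)
            ki, kj = np.unravel_index(idx, (kernel, kernel))
            n_i, c_i, h_i, w_i = np.indices(idx.shape)
            np.add.at(gx, (n_i, c_i, h_i * stride + ki, w_i * stride + kj), g)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accum(gx)

        return self._make(out_data.astype(np.float32), (self,), backward)

    def upsample_nearest2(self):
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)

        def backward(g):
            N, C, H2, W2 = g.shape
            self._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

        return self._make(out_data, (self,), backward)


def _im2col(x_padded, kh, kw, stride, Ho, Wo):
    N, C = x_padded.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(
        x_padded, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, kh, kw) -> (N, C*kh*kw, Ho*Wo)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        N, C * kh * kw, Ho * Wo)


def _col2im(cols, x_shape, kh, kw, stride, Ho, Wo):
    N, C, H, W = x_shape
    gx = np.zeros(x_shape, dtype=np.float32)
    cols = cols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + Ho * stride:stride,
               j:j + Wo * stride:stride] += cols[:, :, i, j]
    return gx


def cat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for i, t in enumerate(tensors):
                t._accum(np.take(g, i, axis=axis))

        out._backward = backward
    return out
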