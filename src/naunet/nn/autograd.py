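"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine providing exactly the operations the segmentation
networks need: stride-1 "same" convolution, 2x2 max pooling, x2 nearest
upsampling, batch normalization, ReLU/sigmoid, channel concatenation,
broadcast arithmetic and reductions.  All computation is float32.

Every operation optionally records a static cost descriptor on an active
:class:`~naunet.nn.profile.Recorder`, which the complexity profiler uses to
account FLOPs and activation memory of a forward pass.
"""

from __future__ import annotations

import numpy as np

# Active profiling recorder (see naunet.nn.profile).  None disables recording.
_RECORDER = None


def _record(kind, **info):
    if _RECORDER is not None:
        _RECORDER.add(kind, **info)


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        arr = np.asarray(data, dtype=np.float32)
        self.data = arr if arr.flags["C_CONTIGUOUS"] else np.ascontiguousarray(arr)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad or self._backward is not None})"


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- arithmetic ------------------------------------------------------------

def add(a, b):
    if not isinstance(b, Tensor):
        a = as_tensor(a)
        data = a.data + np.float32(b)
        _record("add", shape=data.shape)

        def backward(g, a=a):
            a._accumulate(_unbroadcast(g, a.shape))

        return _make(data, [a], backward)
    a, b = as_tensor(a), b
    data = a.data + b.data
    _record("add", shape=data.shape)

    def backward(g, a=a, b=b):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, [a, b], backward)


def mul(a, b):
    a = as_tensor(a)
    if not isinstance(b, Tensor):
        data = a.data * np.float32(b)
        _record("mul", shape=data.shape)

        def backward(g, a=a, s=np.float32(b)):
            a._accumulate(_unbroadcast(g * s, a.shape))

        return _make(data, [a], backward)
    data = a.data * b.data
    _record("mul", shape=data.shape)

    def backward(g, a=a, b=b):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, [a, b], backward)


def div(a, b):
    a = as_tensor(a)
    if not isinstance(b, Tensor):
        return mul(a, 1.0 / float(b))
    data = a.data / b.data

    def backward(g, a=a, b=b):
        a._accumulate(_unbroadcast(g / b.data, a.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(data, [a, b], backward)


def log(a):
    a = as_tensor(a)
    data = np.log(a.data)
    _record("act", shape=data.shape)

    def backward(g, a=a):
        a._accumulate(g / a.data)

    return _make(data, [a], backward)


def clip(a, lo, hi):
    """Clamp values; gradient is passed only through unclamped entries."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g, a=a, mask=mask):
        a._accumulate(g * mask)

    return _make(data, [a], backward)


def tsum(a, axis=None):
    a = as_tensor(a)
    data = np.sum(a.data, axis=axis, keepdims=False)

    def backward(g, a=a, axis=axis):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape))

    return _make(np.asarray(data, dtype=np.float32), [a], backward)


def tmean(a, axis=None):
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis), 1.0 / n)


# -- activations -----------------------------------------------------------

def relu(a):
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)
    _record("act", shape=data.shape)

    def backward(g, a=a):
        a._accumulate(g * (a.data > 0))

    return _make(data, [a], backward)


def sigmoid(a):
    a = as_tensor(a)
    # numerically stable logistic
    data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-a.data)),
                    np.exp(a.data) / (1.0 + np.exp(a.data))).astype(np.float32)
    _record("act", shape=data.shape)

    def backward(g, a=a, y=data):
        a._accumulate(g * y * (1.0 - y))

    return _make(data, [a], backward)


# -- structural ops --------------------------------------------------------

def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    _record("concat", shape=data.shape)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(data, tensors, backward)


def conv2d(x, weight, bias=None, padding=0):
    """Stride-1 2-D convolution (cross-correlation) in NCHW layout.

    ``weight`` has shape (C_out, C_in, k, k).  Output spatial size is
    H + 2*padding - k + 1.  Implemented as k^2 batched GEMMs, one per kernel
    offset, which keeps peak memory low and uses BLAS throughout.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    B, C, H, W = x.shape
    O, C2, kh, kw = weight.shape
    if C != C2:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {C2}")
    Ho, Wo = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d: spatial dims {H}x{W} too small for kernel {kh}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    out = np.zeros((B, O, Ho * Wo), dtype=np.float32)
    for u in range(kh):
        for v in range(kw):
            patch = xp[:, :, u:u + Ho, v:v + Wo].reshape(B, C, Ho * Wo)
            out += np.matmul(weight.data[:, :, u, v], patch)
    out = out.reshape(B, O, Ho, Wo)
    if bias is not None:
        out += bias.data.reshape(1, O, 1, 1)
    _record("conv", k=kh, c_in=C, c_out=O, h_out=Ho, w_out=Wo,
            bias=bias is not None)

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g, x=x, weight=weight, bias=bias, xp_shape=xp.shape,
                 padding=padding, dims=(B, C, O, H, W, Ho, Wo, kh, kw)):
        B, C, O, H, W, Ho, Wo, kh, kw = dims
        gf = g.reshape(B, O, Ho * Wo)
        need_x = x.requires_grad or x._backward is not None
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x.data
        dxp = np.zeros(xp_shape, dtype=np.float32) if need_x else None
        dw = np.zeros_like(weight.data)
        for u in range(kh):
            for v in range(kw):
                patch = xp[:, :, u:u + Ho, v:v + Wo].reshape(B, C, Ho * Wo)
                # (B,O,HW) x (B,HW,C) summed over batch -> (O,C)
                dw[:, :, u, v] = np.einsum("bop,bcp->oc", gf, patch, optimize=True)
                if need_x:
                    contrib = np.matmul(weight.data[:, :, u, v].T, gf)
                    dxp[:, :, u:u + Ho, v:v + Wo] += contrib.reshape(B, C, Ho, Wo)
        weight._accumulate(dw)
        if need_x:
            if padding:
                x._accumulate(dxp[:, :, padding:padding + H, padding:padding + W])
            else:
                x._accumulate(dxp)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


def max_pool2(x):
    """2x2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2: spatial dims ({H}, {W}) must be even")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    _record("pool", c=C, h_out=H // 2, w_out=W // 2)

    def backward(g, x=x, idx=idx, dims=(B, C, H, W)):
        B, C, H, W = dims
        df = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(df, idx[..., None], g[..., None], axis=-1)
        dx = df.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(B, C, H, W))

    return _make(out, [x], backward)


def upsample_nearest2(x):
    """Nearest-neighbour x2 spatial upsampling."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    _record("upsample", c=C, h_out=2 * H, w_out=2 * W)

    def backward(g, x=x, dims=(B, C, H, W)):
        B, C, H, W = dims
        x._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(out, [x], backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.1, eps=1e-5):
    """Batch normalization over (B, H, W) per channel.

    ``running_mean``/``running_var`` are plain NumPy arrays updated in place
    in training mode and used as the statistics in evaluation mode.
    """
    x = as_tensor(x)
    B, C, H, W = x.shape
    _record("bn", c=C, h=H, w=W)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))  # unbiased, torch convention
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
        out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

        def backward(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, n=n, C=C):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            gg = g * gamma.data.reshape(1, C, 1, 1)
            s1 = gg.sum(axis=(0, 2, 3)).reshape(1, C, 1, 1)
            s2 = (gg * xhat).sum(axis=(0, 2, 3)).reshape(1, C, 1, 1)
            dx = (gg - s1 / n - xhat * s2 / n) * inv.reshape(1, C, 1, 1)
            x._accumulate(dx.astype(np.float32))

        return _make(out.astype(np.float32), [x, gamma, beta], backward)

    inv = 1.0 / np.sqrt(running_var + eps)
    xhat = (x.data - running_mean.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, C=C):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        x._accumulate(g * (gamma.data * inv).reshape(1, C, 1, 1))

    return _make(out.astype(np.float32), [x, gamma, beta], backward)
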