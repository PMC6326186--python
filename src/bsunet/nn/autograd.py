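"""Minimal reverse-mode autodiff on NumPy arrays.

Implements exactly the operations the segmentation networks need: 2-D
convolution (stride / dilation / "same" padding), 2x2 max-pooling, nearest
up-sampling, batch normalization, channel concatenation, elementwise add,
ReLU, sigmoid and pixel-wise binary cross-entropy.  Arrays are NCHW float32.

Gradient correctness is verified against central finite differences in the
test suite.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "conv2d", "max_pool2x2", "upsample2x", "batch_norm",
    "concat", "add", "relu", "sigmoid", "bce_loss",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None,
                 name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def __repr__(self):
        return f"Tensor{self.data.shape}"


def _accum(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# convolution

def _same_pad(size, k, stride, dilation):
    eff = dilation * (k - 1) + 1
    out = -(-size // stride)
    total = max((out - 1) * stride + eff - size, 0)
    return total // 2, total - total // 2


def _im2col(xp, k, stride, dilation, oh, ow):
    n, c, _, _ = xp.shape
    s = xp.strides
    shape = (n, c, k, k, oh, ow)
    strides = (s[0], s[1], s[2] * dilation, s[3] * dilation,
               s[2] * stride, s[3] * stride)
    cols = np.lib.stride_tricks.as_strided(xp, shape, strides)
    return np.ascontiguousarray(cols).reshape(n, c * k * k, oh * ow)


def _col2im(dcols, xp_shape, k, stride, dilation, oh, ow):
    n, c, hp, wp = xp_shape
    dxp = np.zeros(xp_shape, dtype=np.float32)
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        hi = i * dilation
        for j in range(k):
            wj = j * dilation
            dxp[:, :, hi:hi + stride * oh:stride,
                wj:wj + stride * ow:stride] += dcols[:, :, i, j]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, dilation: int = 1) -> Tensor:
    """'Same'-padded 2-D convolution (cross-correlation), NCHW.

    weight: (cout, cin, k, k); output spatial size = ceil(input / stride).
    """
    n, cin, h, w = x.data.shape
    cout, cin_w, k, _ = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    ph = _same_pad(h, k, stride, dilation)
    pw = _same_pad(w, k, stride, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), ph, pw))
    oh, ow = -(-h // stride), -(-w // stride)
    cols = _im2col(xp, k, stride, dilation, oh, ow)
    wmat = weight.data.reshape(cout, cin * k * k)
    out = np.matmul(wmat, cols)                       # (n, cout, oh*ow)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1)
    out = out.reshape(n, cout, oh, ow)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gm = g.reshape(n, cout, oh * ow)
        dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
        _accum(weight, dw.reshape(weight.data.shape))
        if bias is not None:
            _accum(bias, gm.sum(axis=(0, 2)))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wmat.T, gm)
            dxp = _col2im(dcols, xp.shape, k, stride, dilation, oh, ow)
            dx = dxp[:, :, ph[0]:ph[0] + h, pw[0]:pw[0] + w]
            _accum(x, dx)

    return Tensor(out, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# pooling / resampling

def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    win = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        _accum(x, dx)

    return Tensor(out, parents=(x,), backward=backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x up-sampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        dx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        _accum(x, dx)

    return Tensor(out, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# normalization

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization.  Updates running stats in place
    when training."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gg = g * gamma.data[None, :, None, None]
            if training:
                # full batch-norm backward through batch statistics
                dxhat_sum = gg.sum(axis=(0, 2, 3))
                dxhat_xhat_sum = (gg * xhat).sum(axis=(0, 2, 3))
                dx = (gg - (dxhat_sum[None, :, None, None]
                            + xhat * dxhat_xhat_sum[None, :, None, None]) / m)
                dx *= inv[None, :, None, None]
            else:
                dx = gg * inv[None, :, None, None]
            _accum(x, dx)

    return Tensor(out.astype(np.float32), parents=(x, gamma, beta),
                  backward=backward)


# ---------------------------------------------------------------------------
# pointwise / structural

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return Tensor(out, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(out, parents=(a, b), backward=backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward=backward)


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean pixel-wise binary cross-entropy against a fixed 0/1 target."""
    t = np.asarray(target, dtype=np.float32)
    p = np.clip(prob.data, eps, 1.0 - eps)
    out = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()

    def backward(g):
        dp = (p - t) / (p * (1.0 - p)) / p.size
        _accum(prob, g * dp)

    return Tensor(out, parents=(prob,), backward=backward)
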