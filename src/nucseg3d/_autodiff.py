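"""Minimal reverse-mode automatic differentiation for volumetric networks.

A small tape-based engine specialized to the handful of operations the
dual-U-Net needs: 3D convolution (stride 1), 2x stride-2 transpose
convolution, 2x max pooling, group normalization, ReLU, channel softmax,
channel concatenation, and the usual reductions/losses. Arrays are
(N, C, Z, Y, X) arrays of a single module-wide dtype (float32 by default;
set ``DTYPE`` to float64 for high-precision gradient checks), with the heavy
lifting done by BLAS through im2col matmuls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "backward",
    "conv3d",
    "conv_transpose3d_2x",
    "maxpool3d_2x",
    "relu",
    "group_norm",
    "softmax_channels",
    "concat_channels",
    "add",
    "scale",
    "mean_squared_error",
    "bce_with_logits",
    "Adam",
]

DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE, order="C")
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _node(data, parents, backward_fn) -> Tensor:
    t = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if t.requires_grad:
        t._parents = tuple(parents)
        t._backward = backward_fn
    return t


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar loss through the tape."""
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p in t._parents:
            visit(p)
        topo.append(t)

    visit(loss)
    loss.grad = np.ones_like(loss.data)
    for t in reversed(topo):
        if t._backward is not None and t.grad is not None:
            t._backward(t.grad)


# ---------------------------------------------------------------- raw helpers


def _corr3d(x, w, pad):
    """Cross-correlation of (N,C,D,H,W) with (O,C,k,k,k), stride 1."""
    n, c, d, h, wd = x.shape
    o, _, k, _, _ = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))  # (N,C,D,H,W,k,k,k)
    dd, hh, ww = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * dd * hh * ww, c * k**3)
    out = cols @ w.reshape(o, c * k**3).T
    return out.reshape(n, dd, hh, ww, o).transpose(0, 4, 1, 2, 3)


def _corr3d_weight_grad(x, gout, k, pad):
    """Gradient of _corr3d w.r.t. the kernel."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    # sum over batch and spatial output positions
    return np.tensordot(gout, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))


# ------------------------------------------------------------------ operators


def _fold_reflect1(gp, axis):
    """Adjoint of 1-voxel reflect padding along one axis."""
    sl = [slice(None)] * gp.ndim
    core = list(sl)
    core[axis] = slice(1, -1)
    g = np.ascontiguousarray(gp[tuple(core)])
    if g.shape[axis] == 1:  # length-1 axis: both pads mirror the single voxel
        return gp.sum(axis=axis, keepdims=True)
    first, last = list(sl), list(sl)
    first[axis], last[axis] = 0, -1
    tgt1, tgt2 = list(sl), list(sl)
    tgt1[axis], tgt2[axis] = 1, -2
    g[tuple(tgt1)] += gp[tuple(first)]
    g[tuple(tgt2)] += gp[tuple(last)]
    return g


def conv3d(x: Tensor, w: Tensor, b: Tensor, pad: int, pad_mode: str = "zeros") -> Tensor:
    """3D convolution, stride 1, cubic kernel; zero or reflect padding.

    Reflect padding (supported for pad == 1) keeps border voxels
    statistically indistinguishable from the interior, avoiding the border
    artifacts zero padding induces in image-to-image networks.
    """
    k = w.data.shape[2]
    if pad_mode == "reflect":
        if pad != 1:
            raise ValueError("reflect padding implemented for pad=1 only")
        xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3, mode="reflect")
        out = _corr3d(xp, w.data, 0) + b.data[None, :, None, None, None]
    else:
        xp = None
        out = _corr3d(x.data, w.data, pad) + b.data[None, :, None, None, None]

    def bwd(g):
        if x.requires_grad:
            wf = np.ascontiguousarray(np.flip(w.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
            if pad_mode == "reflect":
                gxp = _corr3d(g, wf, k - 1)  # gradient w.r.t. the padded input
                for axis in (2, 3, 4):
                    gxp = _fold_reflect1(gxp, axis)
                x.accumulate(gxp)
            else:
                x.accumulate(_corr3d(g, wf, k - 1 - pad))
        if w.requires_grad:
            if pad_mode == "reflect":
                w.accumulate(_corr3d_weight_grad(xp, g, k, 0))
            else:
                w.accumulate(_corr3d_weight_grad(x.data, g, k, pad))
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))

    return _node(out, (x, w, b), bwd)


_OFFSETS2 = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transpose convolution, 2x2x2 kernel, stride 2 (exact 2x upsampling).

    Weight shape (C_in, C_out, 2, 2, 2). With kernel == stride the output
    positions do not overlap, so each offset is an independent 1x1 mixing.
    """
    n, ci, d, h, wd = x.data.shape
    co = w.data.shape[1]
    out = np.empty((n, co, 2 * d, 2 * h, 2 * wd), dtype=DTYPE)
    for a, bb, c in _OFFSETS2:
        m = np.tensordot(x.data, w.data[:, :, a, bb, c], axes=(1, 0))  # (N,D,H,W,Co)
        out[:, :, a::2, bb::2, c::2] = m.transpose(0, 4, 1, 2, 3)
    out += b.data[None, :, None, None, None]

    def bwd(g):
        for a, bb, c in _OFFSETS2:
            gs = g[:, :, a::2, bb::2, c::2]
            if x.requires_grad:
                gx = np.tensordot(gs, w.data[:, :, a, bb, c], axes=(1, 1))
                x.accumulate(gx.transpose(0, 4, 1, 2, 3))
            if w.requires_grad:
                gw = np.tensordot(x.data, gs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                w.grad[:, :, a, bb, c] += gw
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))

    return _node(out, (x, w, b), bwd)


def maxpool3d_2x(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; gradient flows to the (first) argmax."""
    n, c, d, h, w = x.data.shape
    blocks = (
        x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(n, c, d // 2, h // 2, w // 2, 8)
    )
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = (
            gb.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )
        x.accumulate(gx)

    return _node(out, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return _node(out, (x,), bwd)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over channel groups and all spatial positions."""
    n, c, d, h, w = x.data.shape
    g_ = groups
    xg = x.data.reshape(n, g_, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, d, h, w)
    out = gamma.data[None, :, None, None, None] * xhat + beta.data[None, :, None, None, None]

    def bwd(gout):
        if gamma.requires_grad:
            gamma.accumulate((gout * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta.accumulate(gout.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dxhat = (gout * gamma.data[None, :, None, None, None]).reshape(n, g_, -1)
            xh = xhat.reshape(n, g_, -1)
            m = dxhat.shape[2]
            s1 = dxhat.sum(axis=2, keepdims=True)
            s2 = (dxhat * xh).sum(axis=2, keepdims=True)
            dx = inv / m * (m * dxhat - s1 - xh * s2)
            x.accumulate(dx.reshape(n, c, d, h, w))

    return _node(out, (x, gamma, beta), bwd)


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=1, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=1, keepdims=True)
            x.accumulate(out * (g - dot))

    return _node(out, (x,), bwd)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g[:, :ca])
        if b.requires_grad:
            b.accumulate(g[:, ca:])

    return _node(out, (a, b), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return _node(out, (a, b), bwd)


def scale(x: Tensor, s: float) -> Tensor:
    out = x.data * s

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s)

    return _node(out, (x,), bwd)


def mean_squared_error(x: Tensor, target: np.ndarray) -> Tensor:
    diff = x.data - target
    out = np.array(np.mean(diff**2))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * 2.0 * diff / diff.size)

    return _node(out, (x,), bwd)


def bce_with_logits(x: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross entropy on logits; target in [0, 1]."""
    z, t = x.data, target
    out = np.array(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))

    def bwd(g):
        if x.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            x.accumulate(g * (sig - t) / z.size)

    return _node(out, (x,), bwd)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
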