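"""Minimal reverse-mode automatic differentiation over NumPy arrays, with the
3D operations the perfusion-mapping network needs: convolution (via im2col),
transposed convolution, batch normalization, PReLU-family activations,
channelwise (spatial) 3D dropout, sigmoid, concatenation, and a masked binary
cross-entropy loss.

All tensors are float32 with layout ``(N, C, D, H, W)``.  The engine is
deliberately small: operations build a DAG of :class:`Tensor` nodes whose
``_backward`` closures accumulate gradients into their parents; ``backward()``
runs a topological sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = g.astype(np.float32, copy=False)
    t.grad = g.copy() if t.grad is None else t.grad + g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ----------------------------------------------------------------- basics
def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bw)


def mul_const(a: Tensor, c: np.ndarray | float) -> Tensor:
    c = np.asarray(c, dtype=np.float32)

    def bw(g):
        _accum(a, _unbroadcast(g * c, a.data.shape))

    return _node(a.data * c, (a,), bw)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def bw(g):
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    return _node(np.concatenate([a.data, b.data], axis=1), (a, b), bw)


# ------------------------------------------------------------ activations
def prelu(x: Tensor, a: Tensor) -> Tensor:
    """PReLU with per-channel learnable slope ``a`` (shape (C,)):
    y = x for x > 0, a*x otherwise."""
    slope = a.data.reshape(1, -1, 1, 1, 1)
    pos = x.data > 0
    out = np.where(pos, x.data, slope * x.data)

    def bw(g):
        _accum(x, np.where(pos, g, slope * g))
        da = (g * x.data * (~pos)).sum(axis=(0, 2, 3, 4))
        _accum(a, da.reshape(a.data.shape))

    return _node(out, (x, a), bw)


def leaky_relu(x: Tensor, slope: float) -> Tensor:
    """Fixed-slope rectifier; slope=0 gives plain ReLU."""
    pos = x.data > 0
    out = np.where(pos, x.data, np.float32(slope) * x.data)

    def bw(g):
        _accum(x, np.where(pos, g, np.float32(slope) * g))

    return _node(out, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data).astype(np.float32)

    def bw(g):
        _accum(x, g * y * (1.0 - y))

    return _node(y, (x,), bw)


def dropout3d(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Spatial (channelwise) dropout: whole feature channels are zeroed."""
    if not training or p <= 0:
        return x
    n, c = x.data.shape[:2]
    keep = (rng.random((n, c, 1, 1, 1)) >= p).astype(np.float32) / np.float32(1.0 - p)

    def bw(g):
        _accum(x, g * keep)

    return _node(x.data * keep, (x,), bw)


# ----------------------------------------------------------- convolutions
def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N, C, D, H, W) into (N*Do*Ho*Wo, C*k^3) columns whose flat
    order matches ``w.reshape(Cout, -1)``.  Built by k^3 block copies of a
    channel-last transpose (contiguous inner axis) — much cheaper than an
    elementwise gather of the 8D sliding-window view."""
    n, c, d, h, wd = x.shape
    dp, hp, wp = d + 2 * pad, h + 2 * pad, wd + 2 * pad
    do = (dp - k) // stride + 1
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    # channel-last padded copy in one pass
    xt = np.zeros((n, dp, hp, wp, c), dtype=np.float32)
    xt[:, pad : pad + d, pad : pad + h, pad : pad + wd, :] = x.transpose(0, 2, 3, 4, 1)
    cols = np.empty((n, do, ho, wo, k * k * k, c), dtype=np.float32)
    idx = 0
    for a_ in range(k):
        for b_ in range(k):
            for c_ in range(k):
                cols[:, :, :, :, idx, :] = xt[
                    :,
                    a_ : a_ + stride * do : stride,
                    b_ : b_ + stride * ho : stride,
                    c_ : c_ + stride * wo : stride,
                    :,
                ]
                idx += 1
    return cols.reshape(n * do * ho * wo, k * k * k * c), (do, ho, wo), (dp, hp, wp)


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int | None = None) -> Tensor:
    """3D cross-correlation.  ``w``: (Cout, Cin, k, k, k); default padding is
    'same' for stride 1 (k odd), 0 for strided convolutions."""
    cout, cin, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if pad is None:
        pad = k // 2 if stride == 1 else 0
    n = x.data.shape[0]
    cols, (do, ho, wo), padded_sp = _im2col(x.data, k, stride, pad)
    # weight flattened in the (k^3, Cin) order the columns use
    wmat = np.ascontiguousarray(
        w.data.transpose(0, 2, 3, 4, 1).reshape(cout, -1)
    )
    out = cols @ wmat.T + b.data
    out = np.ascontiguousarray(
        out.reshape(n, do, ho, wo, cout).transpose(0, 4, 1, 2, 3)
    )

    def bw(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, cout)
        dw = (gcols.T @ cols).reshape(cout, k, k, k, cin).transpose(0, 4, 1, 2, 3)
        _accum(w, dw)
        _accum(b, gcols.sum(axis=0))
        if x.requires_grad:
            dcols = (gcols @ wmat).reshape(n, do, ho, wo, k * k * k, cin)
            dxt = np.zeros((n, *padded_sp, cin), dtype=np.float32)
            idx = 0
            for a_ in range(k):
                for b_ in range(k):
                    for c_ in range(k):
                        dxt[
                            :,
                            a_ : a_ + stride * do : stride,
                            b_ : b_ + stride * ho : stride,
                            c_ : c_ + stride * wo : stride,
                            :,
                        ] += dcols[:, :, :, :, idx, :]
                        idx += 1
            dxp = dxt.transpose(0, 4, 1, 2, 3)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            _accum(x, np.ascontiguousarray(dxp))

    return _node(out, (x, w, b), bw)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel = stride (non-overlapping
    upsampling).  ``w``: (Cin, Cout, s, s, s)."""
    s = w.data.shape[2]
    if s != stride:
        raise ValueError("conv_transpose3d requires kernel == stride")
    n, cin, d, h, ww = x.data.shape
    cout = w.data.shape[1]
    out = np.empty((n, cout, d * s, h * s, ww * s), dtype=np.float32)
    xt = x.data.transpose(0, 2, 3, 4, 1)  # (N, D, H, W, Cin)
    for a_ in range(s):
        for b_ in range(s):
            for c_ in range(s):
                y = xt @ w.data[:, :, a_, b_, c_]  # (N, D, H, W, Cout)
                out[:, :, a_::s, b_::s, c_::s] = y.transpose(0, 4, 1, 2, 3)
    out += b.data.reshape(1, cout, 1, 1, 1)

    def bw(g):
        dw = np.zeros_like(w.data)
        dx = np.zeros_like(x.data) if x.requires_grad else None
        for a_ in range(s):
            for b_ in range(s):
                for c_ in range(s):
                    gt = g[:, :, a_::s, b_::s, c_::s].transpose(0, 2, 3, 4, 1)
                    dw[:, :, a_, b_, c_] = np.tensordot(
                        xt, gt, axes=([0, 1, 2, 3], [0, 1, 2, 3])
                    )
                    if dx is not None:
                        dx += (gt @ w.data[:, :, a_, b_, c_].T).transpose(0, 4, 1, 2, 3)
        _accum(w, dw)
        _accum(b, g.sum(axis=(0, 2, 3, 4)))
        if dx is not None:
            _accum(x, dx)

    return _node(out, (x, w, b), bw)


# -------------------------------------------------------------- batchnorm
def batchnorm3d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    axes = (0, 2, 3, 4)
    gshape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mu.reshape(gshape)) * inv_std.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def bw(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        if not x.requires_grad:
            return
        gi = gamma.data.reshape(gshape) * inv_std.reshape(gshape)
        if training:
            gx = g - g.mean(axis=axes, keepdims=True) - xhat * (g * xhat).mean(
                axis=axes, keepdims=True
            )
            _accum(x, gi * gx)
        else:
            _accum(x, gi * g)

    return _node(out, (x, gamma, beta), bw)


# ------------------------------------------------------------------- loss
def masked_bce(pred: Tensor, target: np.ndarray, mask: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over in-mask voxels, with soft targets.
    Predictions are clamped to [eps, 1-eps], so the loss is always finite."""
    m = np.broadcast_to(np.asarray(mask, dtype=bool), pred.data.shape)
    n_eff = int(m.sum())
    if n_eff == 0:
        raise ValueError("empty mask in BCE loss")
    p = np.clip(pred.data, eps, 1.0 - eps)
    t = np.broadcast_to(np.asarray(target, dtype=np.float32), pred.data.shape)
    per_vox = -(t * np.log(p) + (1.0 - t) * np.log1p(-p))
    loss = per_vox[m].mean()

    def bw(g):
        d = np.zeros_like(pred.data)
        d[m] = ((-(t / p) + (1.0 - t) / (1.0 - p))[m]) / n_eff
        _accum(pred, g * d)

    return _node(np.float32(loss), (pred,), bw)
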