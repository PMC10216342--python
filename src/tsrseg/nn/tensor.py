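"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations needed by the segmentation networks are provided:
2-D (and depthwise) convolution, batch normalization, ReLU/ReLU6,
residual add, channel concatenation, nearest-neighbour 2x upsampling,
masked average pooling, prototype similarity scoring and the loss
primitives. Everything is float64 so that downstream prototype and
similarity arithmetic can be compared against independent oracles at
tight tolerances.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "backward",
    "conv2d", "depthwise_conv2d", "batch_norm", "relu", "relu6",
    "add", "concat", "upsample2x", "masked_mean", "stack_vectors",
    "mean_vectors", "proto_scores", "log_softmax", "weighted_nll",
    "inner", "combine",
]


class Tensor:
    """Node in the computation graph: value, gradient and backward rule."""

    __slots__ = ("data", "grad", "parents", "_bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._bwd = bwd
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar loss through the graph."""
    if loss.data.ndim != 0 and loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._bwd is not None and node.grad is not None:
            node._bwd(node.grad)


# ---------------------------------------------------------------- helpers

def _pad(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp, kh, kw, s, oh, ow):
    """View of sliding windows, shape (N, C, kh, kw, OH, OW)."""
    n, c, _, _ = xp.shape
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, oh, ow), (sn, sc, sh, sw, sh * s, sw * s),
        writeable=False)


def _out_size(h, k, s, p):
    return (h + 2 * p - k) // s + 1


# ------------------------------------------------------------------- ops

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW; w is (F, C, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    f, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    oh, ow = _out_size(h, kh, stride, pad), _out_size(wid, kw, stride, pad)
    if kh == 1 and kw == 1 and pad == 0:
        xs = xd[:, :, ::stride, ::stride]
        out = np.einsum("fc,nchw->nfhw", wd[:, :, 0, 0], xs, optimize=True)
        cols = None
    else:
        xp = _pad(xd, pad)
        cols = np.ascontiguousarray(_windows(xp, kh, kw, stride, oh, ow))
        out = np.einsum("fckl,ncklhw->nfhw", wd, cols, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, parents)

    def bwd(g):
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if kh == 1 and kw == 1 and pad == 0:
            xs = xd[:, :, ::stride, ::stride]
            dw = np.einsum("nfhw,nchw->fc", g, xs, optimize=True)
            w._accumulate(dw[:, :, None, None])
            dxs = np.einsum("fc,nfhw->nchw", wd[:, :, 0, 0], g, optimize=True)
            if stride == 1:
                x._accumulate(dxs)
            else:
                dx = np.zeros_like(xd)
                dx[:, :, ::stride, ::stride] = dxs
                x._accumulate(dx)
            return
        dw = np.einsum("nfhw,ncklhw->fckl", g, cols, optimize=True)
        w._accumulate(dw)
        dcols = np.einsum("fckl,nfhw->ncklhw", wd, g, optimize=True)
        hp, wp = h + 2 * pad, wid + 2 * pad
        dxp = np.zeros((n, c, hp, wp))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + stride * oh:stride,
                    j:j + stride * ow:stride] += dcols[:, :, i, j]
        x._accumulate(dxp[:, :, pad:hp - pad or None, pad:wp - pad or None]
                      if pad else dxp)

    res._bwd = bwd
    return res


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1,
                     pad: int = 1) -> Tensor:
    """Depthwise 3x3-style convolution; w is (C, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError("depthwise channel mismatch")
    oh, ow = _out_size(h, kh, stride, pad), _out_size(wid, kw, stride, pad)
    xp = _pad(xd, pad)
    out = np.zeros((n, c, oh, ow))
    for i in range(kh):
        for j in range(kw):
            out += (xp[:, :, i:i + stride * oh:stride,
                       j:j + stride * ow:stride]
                    * wd[:, i, j][None, :, None, None])
    res = Tensor(out, (x, w))

    def bwd(g):
        dw = np.zeros_like(wd)
        hp, wp = h + 2 * pad, wid + 2 * pad
        dxp = np.zeros((n, c, hp, wp))
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + stride * oh:stride,
                           j:j + stride * ow:stride]
                dw[:, i, j] = (g * patch).sum(axis=(0, 2, 3))
                dxp[:, :, i:i + stride * oh:stride,
                    j:j + stride * ow:stride] += (
                    g * wd[:, i, j][None, :, None, None])
        w._accumulate(dw)
        x._accumulate(dxp[:, :, pad:hp - pad or None, pad:wp - pad or None]
                      if pad else dxp)

    res._bwd = bwd
    return res


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, state: dict,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization with running statistics."""
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        state["mean"] = (1 - momentum) * state["mean"] + momentum * mu
        state["var"] = (1 - momentum) * state["var"] + momentum * var
    else:
        mu, var = state["mean"], state["var"]
    std = np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    res = Tensor(out, (x, gamma, beta))

    def bwd(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            m = dxhat.mean(axis=(0, 2, 3), keepdims=True)
            mx = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            dx = (dxhat - m - xhat * mx) / std[None, :, None, None]
        else:
            dx = dxhat / std[None, :, None, None]
        x._accumulate(dx)

    res._bwd = bwd
    return res


def _clip_act(x: Tensor, lo, hi) -> Tensor:
    out = np.clip(x.data, lo, hi)
    mask = (x.data > lo) if hi is None else ((x.data > lo) & (x.data < hi))
    res = Tensor(out, (x,))
    res._bwd = lambda g: x._accumulate(g * mask)
    return res


def relu(x: Tensor) -> Tensor:
    return _clip_act(x, 0.0, None)


def relu6(x: Tensor) -> Tensor:
    return _clip_act(x, 0.0, 6.0)


def add(a: Tensor, b: Tensor) -> Tensor:
    res = Tensor(a.data + b.data, (a, b))

    def bwd(g):
        a._accumulate(g)
        b._accumulate(g)

    res._bwd = bwd
    return res


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.data.shape[1]
    res = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def bwd(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    res._bwd = bwd
    return res


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    res = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    res._bwd = bwd
    return res


def masked_mean(feat: Tensor, weights: np.ndarray) -> Tensor:
    """Weighted spatial mean: (N,C,h,w) features x (N,h,w) weights -> (C,)."""
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("masked_mean: weights sum to zero")
    out = np.einsum("nchw,nhw->c", feat.data, weights, optimize=True) / wsum
    res = Tensor(out, (feat,))

    def bwd(g):
        feat._accumulate(np.einsum("c,nhw->nchw", g / wsum, weights,
                                   optimize=True))

    res._bwd = bwd
    return res


def stack_vectors(vectors: list[Tensor]) -> Tensor:
    """Stack K vectors of length C into a (K, C) tensor."""
    res = Tensor(np.stack([v.data for v in vectors]), tuple(vectors))

    def bwd(g):
        for k, v in enumerate(vectors):
            v._accumulate(g[k])

    res._bwd = bwd
    return res


def mean_vectors(vectors: list[Tensor]) -> Tensor:
    """Unweighted mean of equally shaped tensors."""
    k = len(vectors)
    res = Tensor(sum(v.data for v in vectors) / k, tuple(vectors))

    def bwd(g):
        for v in vectors:
            v._accumulate(g / k)

    res._bwd = bwd
    return res


def proto_scores(feat: Tensor, protos: Tensor) -> Tensor:
    """Similarity -0.5*||f - p||^2 per cell: (N,C,h,w) x (K,C) -> (N,K,h,w)."""
    f, p = feat.data, protos.data
    f2 = (f ** 2).sum(axis=1)                      # (N,h,w)
    p2 = (p ** 2).sum(axis=1)                      # (K,)
    fp = np.einsum("nchw,kc->nkhw", f, p, optimize=True)
    s = fp - 0.5 * f2[:, None] - 0.5 * p2[None, :, None, None]
    res = Tensor(s, (feat, protos))

    def bwd(g):
        gs = g.sum(axis=1)                          # (N,h,w)
        df = np.einsum("nkhw,kc->nchw", g, p, optimize=True) \
            - f * gs[:, None]
        dp = np.einsum("nkhw,nchw->kc", g, f, optimize=True) \
            - p * g.sum(axis=(0, 2, 3))[:, None]
        feat._accumulate(df)
        protos._accumulate(dp)

    res._bwd = bwd
    return res


def log_softmax(x: Tensor) -> Tensor:
    """Log-softmax over the class axis (axis 1)."""
    m = x.data.max(axis=1, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    lp = z - lse
    res = Tensor(lp, (x,))

    def bwd(g):
        sm = np.exp(lp)
        x._accumulate(g - sm * g.sum(axis=1, keepdims=True))

    res._bwd = bwd
    return res


def weighted_nll(logp: Tensor, targets: np.ndarray,
                 mask: np.ndarray) -> Tensor:
    """Cross-entropy of log-probabilities against (fractional) targets.

    targets: (N,K,h,w) nonnegative weights per class; mask: (N,h,w) cell
    inclusion weights. Returns the mask-weighted mean cross-entropy.
    """
    msum = mask.sum()
    if msum <= 0:
        raise ValueError("weighted_nll: empty mask")
    ce = -(targets * logp.data).sum(axis=1)
    res = Tensor((ce * mask).sum() / msum, (logp,))

    def bwd(g):
        logp._accumulate(-g * targets * mask[:, None] / msum)

    res._bwd = bwd
    return res


def inner(x: Tensor, w: np.ndarray) -> Tensor:
    """Scalar inner product sum(x * w) with a constant weight array."""
    res = Tensor((x.data * w).sum(), (x,))
    res._bwd = lambda g: x._accumulate(g * w)
    return res


def combine(terms: list[tuple[float, Tensor]]) -> Tensor:
    """Scalar linear combination sum(coef * scalar-tensor)."""
    val = sum(c * t.data for c, t in terms)
    res = Tensor(val, tuple(t for _, t in terms))

    def bwd(g):
        for c, t in terms:
            t._accumulate(g * c)

    res._bwd = bwd
    return res
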