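"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the dual-branch EEG classifier
needs: 1-D "same"-padded convolutions expressed as unfold + matmul, the
depthwise spatial collapse over electrodes, separable (depthwise temporal +
pointwise) convolution, pooling, batch-norm building blocks, the CBAM
pool/MLP/sigmoid algebra and a fused softmax cross-entropy.  Tensors carry a
``requires_grad`` flag and a backward closure; ``Tensor.backward`` runs a
topological sweep.  Float32 is the working precision; float64 inputs are kept
as float64 so numerical gradient checks can run at full precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "neg", "sub", "powf", "reshape", "moveaxis",
    "concat", "mean", "amax", "dot_last", "unfold_last", "avgpool_last",
    "spatial_collapse", "per_filter_dot", "pointwise", "sigmoid", "relu",
    "elu", "softmax", "softmax_cross_entropy",
]


def _as_array(data):
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, other)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                  _backward=backward if req else None)


# Elementwise -------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = _wrap(a)

    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward)


def sub(a, b):
    return add(a, neg(_wrap(b)))


def powf(a, p: float):
    """Elementwise power with constant exponent (positive base assumed)."""
    a = _wrap(a)
    out_data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def elu(a, alpha: float = 1.0):
    a = _wrap(a)
    pos = a.data > 0
    expm1 = alpha * np.expm1(np.minimum(a.data, 0.0))
    out_data = np.where(pos, a.data, expm1)

    def backward(g):
        _accum(a, g * np.where(pos, 1.0, expm1 + alpha))

    return _make(out_data, (a,), backward)


# Shape manipulation ------------------------------------------------

def reshape(a, shape):
    a = _wrap(a)
    orig = a.shape

    def backward(g):
        _accum(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def moveaxis(a, src, dst):
    a = _wrap(a)

    def backward(g):
        _accum(a, np.moveaxis(g, dst, src))

    return _make(np.moveaxis(a.data, src, dst), (a,), backward)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, backward)


# Reductions --------------------------------------------------------

def mean(a, axes, keepdims=True):
    a = _wrap(a)
    axes = tuple(axes)
    n = int(np.prod([a.shape[ax] for ax in axes]))
    out_data = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g / n, a.shape).copy())

    return _make(out_data, (a,), backward)


def amax(a, axes, keepdims=True):
    a = _wrap(a)
    axes = tuple(axes)
    out_data = a.data.max(axis=axes, keepdims=True)
    mask = a.data == out_data
    counts = mask.sum(axis=axes, keepdims=True)
    res = out_data if keepdims else out_data.squeeze(axis=axes)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, mask * (g / counts))

    return _make(res, (a,), backward)


# Linear algebra ----------------------------------------------------

def dot_last(x, w):
    """``y[..., j] = sum_k x[..., k] * w[k, j]`` (matmul over the last axis)."""
    x, w = _wrap(x), _wrap(w)
    out_data = x.data @ w.data

    def backward(g):
        _accum(x, g @ w.data.T)
        xf = x.data.reshape(-1, x.shape[-1])
        gf = g.reshape(-1, g.shape[-1])
        _accum(w, xf.T @ gf)

    return _make(out_data, (x, w), backward)


# Convolution primitives --------------------------------------------

def _same_pad(k: int):
    return (k - 1) // 2, k // 2


def unfold_last(x, k: int):
    """Sliding windows of width ``k`` along the last axis with 'same' padding.

    (..., T) -> (..., T, k); window t covers padded samples [t, t+k).
    """
    x = _wrap(x)
    pl, pr = _same_pad(k)
    T = x.shape[-1]
    pad_width = [(0, 0)] * (x.ndim - 1) + [(pl, pr)]
    padded = np.pad(x.data, pad_width)
    win = np.lib.stride_tricks.sliding_window_view(padded, k, axis=-1)
    out_data = np.ascontiguousarray(win)  # (..., T, k)

    def backward(g):
        gp = np.zeros(padded.shape, dtype=g.dtype)
        for j in range(k):
            gp[..., j:j + T] += g[..., :, j]
        _accum(x, gp[..., pl:pl + T])

    return _make(out_data, (x,), backward)


def avgpool_last(x, p: int):
    """Average pooling with width/stride ``p`` over the last axis (floor)."""
    x = _wrap(x)
    T = x.shape[-1]
    Tp = (T // p) * p
    lead = x.shape[:-1]
    out_data = x.data[..., :Tp].reshape(lead + (T // p, p)).mean(axis=-1)

    def backward(g):
        gx = np.zeros(x.shape, dtype=g.dtype)
        gx[..., :Tp] = np.repeat(g / p, p, axis=-1)
        _accum(x, gx)

    return _make(out_data, (x,), backward)


def spatial_collapse(x, w):
    """Depthwise convolution spanning all electrodes.

    x: (B, C, T, F) feature stack, w: (F, C, D) one C-long kernel per
    (temporal filter, depth) pair -> (B, F, D, T).  The electrode axis is
    fully collapsed ('valid' over height), matching the classifier's
    depthwise spatial stage.  Implemented as a batched matmul over (B, F).
    """
    x, w = _wrap(x), _wrap(w)
    xt = np.ascontiguousarray(np.moveaxis(x.data, 3, 1))  # (B, F, C, T)
    wt = np.ascontiguousarray(w.data.transpose(0, 2, 1))  # (F, D, C)
    out_data = np.matmul(wt[None], xt)                    # (B, F, D, T)

    def backward(g):
        # (1, F, C, D) @ (B, F, D, T) -> (B, F, C, T)
        gxt = np.matmul(w.data[None], g)
        _accum(x, np.moveaxis(gxt, 1, 3))
        # sum_b (B, F, C, T) @ (B, F, T, D) -> (F, C, D)
        gw = np.matmul(xt, np.ascontiguousarray(g.transpose(0, 1, 3, 2)))
        _accum(w, gw.sum(axis=0))

    return _make(out_data, (x, w), backward)


def batchnorm_train(x, gamma, beta, axes, eps: float):
    """Fused training-mode batch normalization.

    Normalizes over ``axes``; ``gamma``/``beta`` broadcast against the
    input.  Returns (output, batch_mean, batch_var) with the statistics as
    plain numpy arrays for the caller's running-average update.
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = tuple(axes)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if beta.requires_grad:
            _accum(beta, _unbroadcast(g, beta.shape))
        gx_hat_prod = g * xhat
        if gamma.requires_grad:
            _accum(gamma, _unbroadcast(gx_hat_prod, gamma.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            _accum(x, inv * (gh - m1 - xhat * m2))

    out = _make(out_data, (x, gamma, beta), backward)
    return out, mu, var


def per_filter_dot(x, w):
    """Depthwise temporal convolution step: (B, F, W, K) x (F, K) -> (B, F, W)."""
    x, w = _wrap(x), _wrap(w)
    out_data = np.einsum("bfwk,fk->bfw", x.data, w.data, optimize=True)

    def backward(g):
        _accum(x, g[..., None] * w.data[None, :, None, :])
        _accum(w, np.einsum("bfwk,bfw->fk", x.data, g, optimize=True))

    return _make(out_data, (x, w), backward)


def pointwise(x, w):
    """Pointwise (1x1) convolution over the filter axis: (B, F, W) x (F, G) -> (B, G, W)."""
    x, w = _wrap(x), _wrap(w)
    out_data = np.einsum("bfw,fg->bgw", x.data, w.data, optimize=True)

    def backward(g):
        _accum(x, np.einsum("bgw,fg->bfw", g, w.data, optimize=True))
        _accum(w, np.einsum("bfw,bgw->fg", x.data, g, optimize=True))

    return _make(out_data, (x, w), backward)


# Classifier head ---------------------------------------------------

def softmax(logits):
    logits = _wrap(logits)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        _accum(logits, p * (g - dot))

    return _make(p, (logits,), backward)


def softmax_cross_entropy(logits, onehot):
    """Mean categorical cross-entropy; ``onehot`` is a constant (B, N) array."""
    logits = _wrap(logits)
    y = np.asarray(onehot, dtype=logits.data.dtype)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    B = logits.shape[0]
    loss = float(-(y * np.log(np.maximum(p, 1e-12))).sum() / B)

    def backward(g):
        _accum(logits, g * (p - y) / B)

    return _make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)
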