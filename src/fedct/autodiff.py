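"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operators the tiny 3D networks need: same-padding 3D
convolution, 2x average pooling / nearest upsampling, ReLU, linear layers,
batched matmul, softmax, layer norm, and the CE/Dice losses.  Tensors hold
float64 data; gradients accumulate into ``.grad``.  ``backward`` runs a
topological sort from the scalar loss.

This is intentionally small and fully deterministic (pure numpy, no
threading-order ambiguity at these sizes); every operator's gradient is
covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple["Tensor", ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() must start from a scalar")
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

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'}, name={self.name!r})"


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = live
    out._backward = backward if live else None
    out.requires_grad = bool(live)
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / structural ops


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(g, b.data.shape))
    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(g * a.data, b.data.shape))
    return _node(a.data * b.data, (a, b), bw)


def scale(a: Tensor, s: float) -> Tensor:
    def bw(g):
        a._accum(g * s)
    return _node(a.data * s, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def bw(g):
        a._accum(g * mask)
    return _node(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    s = _sigmoid(a.data)
    def bw(g):
        a._accum(g * s * (1.0 - s))
    return _node(s, (a,), bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    def bw(g):
        a._accum(g.reshape(orig))
    return _node(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    def bw(g):
        a._accum(g.transpose(inv))
    return _node(a.data.transpose(axes), (a,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    def bw(g):
        a._accum(np.full_like(a.data, float(g) / n))
    return _node(np.array(a.data.mean()), (a,), bw)


# ---------------------------------------------------------------------------
# dense / attention ops


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (..., Din) @ w: (Din, Dout) + b."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data
    def bw(g):
        if x.requires_grad or x._parents:
            x._accum(g @ w.data.T)
        if w.requires_grad:
            din, dout = w.data.shape
            w._accum(x.data.reshape(-1, din).T @ g.reshape(-1, dout))
        if b is not None and b.requires_grad:
            b._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul on the last two axes."""
    def bw(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))
    return _node(a.data @ b.data, (a, b), bw)


def softmax(a: Tensor) -> Tensor:
    """Softmax over the last axis."""
    x = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(x)
    s = e / e.sum(axis=-1, keepdims=True)
    def bw(g):
        a._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))
    return _node(s, (a,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer norm over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data
    n = x.data.shape[-1]
    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, n).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, n).sum(axis=0))
        if x.requires_grad or x._parents:
            gx_hat = g * gamma.data
            gx = inv * (gx_hat - gx_hat.mean(axis=-1, keepdims=True)
                        - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True))
            x._accum(gx)
    return _node(out, (x, gamma, beta), bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of a (C, D, H, W) map."""
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    g4 = gamma.data[:, None, None, None]
    out = xhat * g4 + beta.data[:, None, None, None]
    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=ax))
        if beta.requires_grad:
            beta._accum(g.sum(axis=ax))
        if x.requires_grad or x._parents:
            gxh = g * g4
            x._accum(inv * (gxh - gxh.mean(axis=ax, keepdims=True)
                            - xhat * (gxh * xhat).mean(axis=ax, keepdims=True)))
    return _node(out, (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# 3D image ops (channel-first, no batch axis: (C, D, H, W))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 3D convolution; kernel (O, C, k, k, k), odd k."""
    k = w.data.shape[2]
    p = k // 2
    if p:
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    else:
        xp = x.data
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    out = np.einsum("cdhwijl,ocijl->odhw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[:, None, None, None]
    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("cdhwijl,odhw->ocijl", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))
        if x.requires_grad or x._parents:
            gp = np.pad(g, ((0, 0), (p, p), (p, p), (p, p))) if p else g
            gwin = sliding_window_view(gp, (k, k, k), axis=(1, 2, 3))
            wf = w.data[:, :, ::-1, ::-1, ::-1]
            x._accum(np.einsum("odhwijl,ocijl->cdhw", gwin, wf, optimize=True))
    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


def avg_pool2(x: Tensor) -> Tensor:
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(d, h, w)}")
    out = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
    def bw(g):
        ge = np.repeat(np.repeat(np.repeat(g / 8.0, 2, axis=1), 2, axis=2), 2, axis=3)
        x._accum(ge)
    return _node(out, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), 2, axis=3)
    c, d, h, w = x.data.shape
    def bw(g):
        x._accum(g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)))
    return _node(out, (x,), bw)


# ---------------------------------------------------------------------------
# losses


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with soft targets, numerically stable."""
    x = logits.data
    t = np.asarray(target, dtype=float)
    loss = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    n = x.size
    def bw(g):
        logits._accum((float(g) / n) * (_sigmoid(x) - t))
    return _node(np.array(loss.mean()), (logits,), bw)


def soft_dice_loss(logits: Tensor, target: np.ndarray, eps: float = 1e-5) -> Tensor:
    """1 - mean soft Dice over channels; sigmoid activation, eps-smoothed."""
    x = logits.data
    t = np.asarray(target, dtype=float)
    p = _sigmoid(x)
    ax = tuple(range(1, x.ndim))
    s1 = (p * t).sum(axis=ax)
    s2 = p.sum(axis=ax)
    s3 = t.sum(axis=ax)
    denom = s2 + s3 + eps
    dice = (2.0 * s1 + eps) / denom
    nchan = x.shape[0]
    def bw(g):
        sh = (slice(None),) + (None,) * (x.ndim - 1)
        ddice_dp = (2.0 * t * denom[sh] - (2.0 * s1 + eps)[sh]) / (denom**2)[sh]
        logits._accum(-(float(g) / nchan) * ddice_dp * p * (1.0 - p))
    return _node(np.array(1.0 - dice.mean()), (logits,), bw)


__all__ = [
    "Tensor", "add", "mul", "scale", "relu", "sigmoid", "reshape", "transpose",
    "concat", "mean_all", "linear", "matmul", "softmax", "layer_norm",
    "conv3d", "avg_pool2", "upsample2", "instance_norm",
    "bce_with_logits", "soft_dice_loss",
]
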