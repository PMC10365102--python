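"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and a
backward closure.  Calling :meth:`Tensor.backward` on a scalar loss walks the
recorded computation graph in reverse topological order and accumulates
gradients into every tensor created with ``requires_grad=True``.

Only the operations needed by the segmentation network are provided:
elementwise arithmetic, (batched) matrix products, 2-D convolution, pooling and
nearest-neighbour upsampling, batch/layer normalisation, softmax, GELU/ReLU,
dropout, concatenation and a fused softmax cross-entropy.  Everything runs on
the CPU and is deterministic given seeded generators.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "relu", "gelu", "reshape", "transpose",
    "concat", "softmax", "tsum", "conv2d", "avg_pool2", "upsample_nearest2",
    "batch_norm2d", "layer_norm", "dropout", "softmax_cross_entropy",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bwd
    return out


def matmul(a, b) -> Tensor:
    """Batched matrix product ``a @ b`` with broadcasting over leading axes."""
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bwd
    return out


def relu(x) -> Tensor:
    x = _wrap(x)
    out = Tensor(np.maximum(x.data, 0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * (x.data > 0))

    out._backward = bwd
    return out


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x) -> Tensor:
    """GELU with the tanh approximation (transformer MLP activation)."""
    x = _wrap(x)
    v = x.data
    inner = _GELU_C * (v + 0.044715 * v ** 3)
    t = np.tanh(inner)
    out = Tensor(0.5 * v * (1.0 + t), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dinner = _GELU_C * (1.0 + 3 * 0.044715 * v ** 2)
            dx = 0.5 * (1.0 + t) + 0.5 * v * (1.0 - t ** 2) * dinner
            x.accumulate(g * dx)

    out._backward = bwd
    return out


# -- shape manipulation ----------------------------------------------------

def reshape(x, shape) -> Tensor:
    x = _wrap(x)
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    out._backward = bwd
    return out


def transpose(x, axes) -> Tensor:
    x = _wrap(x)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = Tensor(x.data.transpose(axes), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g.transpose(inv))

    out._backward = bwd
    return out


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x.accumulate(np.broadcast_to(g, x.data.shape).astype(x.data.dtype))

    out._backward = bwd
    return out


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out._backward = bwd
    return out


# -- softmax ---------------------------------------------------------------

def softmax(x, axis: int = -1) -> Tensor:
    x = _wrap(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gy = g * y
            x.accumulate(gy - y * gy.sum(axis=axis, keepdims=True))

    out._backward = bwd
    return out


# -- convolution and resampling -------------------------------------------

def conv2d(x, w, b=None) -> Tensor:
    """Stride-1, same-padded 2-D convolution.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw) with odd kh=kw;
    ``b``: (Cout,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    bt = _wrap(b) if b is not None else None
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    ph, pw = kh // 2, kw // 2
    if (ph, pw) == (0, 0):
        xp = x.data
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, h * wd, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    y = cols @ wmat.T                                    # N,HW,Cout
    y = y.transpose(0, 2, 1).reshape(n, cout, h, wd)
    if bt is not None:
        y = y + bt.data[None, :, None, None]
    parents = (x, w) if bt is None else (x, w, bt)
    out = Tensor(y, parents=parents)

    def bwd(g):
        g2 = g.reshape(n, cout, h * wd)                  # N,Cout,HW
        if bt is not None and bt.requires_grad:
            bt.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            # sum over batch and positions: (Cout, Cin*kh*kw)
            gw = np.einsum("ncp,npk->ck", g2, cols)
            w.accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.einsum("ncp,ck->npk", g2, wmat)   # N,HW,Cin*kh*kw
            gcols = gcols.reshape(n, h, wd, cin, kh, kw)
            gxp = np.zeros((n, cin, h + 2 * ph, wd + 2 * pw), dtype=g.dtype)
            for i in range(kh):                          # col2im scatter-add
                for j in range(kw):
                    gxp[:, :, i:i + h, j:j + wd] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if (ph, pw) == (0, 0):
                x.accumulate(gxp)
            else:
                x.accumulate(gxp[:, :, ph:ph + h, pw:pw + wd])

    out._backward = bwd
    return out


def avg_pool2(x) -> Tensor:
    """2x2 average pooling with stride 2 (spatial sides must be even)."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial sides")
    y = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x.accumulate(gx)

    out._backward = bwd
    return out


def upsample_nearest2(x) -> Tensor:
    """2x nearest-neighbour upsampling."""
    x = _wrap(x)
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x.accumulate(gx)

    out._backward = bwd
    return out


# -- normalisation ---------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays mutated in place during
    training (exponential moving average with the given momentum).
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    ax = (0, 2, 3)
    gshape = (1, -1, 1, 1)
    if training:
        mean = x.data.mean(axis=ax)
        var = x.data.var(axis=ax)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        # unbiased variance in the running estimate, biased in the batch step
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) / std.reshape(gshape)
    y = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
    out = Tensor(y, parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=ax))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=ax))
        if x.requires_grad:
            gs = gamma.data.reshape(gshape) / std.reshape(gshape)
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gmean = g.mean(axis=ax).reshape(gshape)
                gxhat_mean = (g * xhat).mean(axis=ax).reshape(gshape)
                x.accumulate(gs * (g - gmean - xhat * gxhat_mean))
            else:
                x.accumulate(gs * g)

    out._backward = bwd
    return out


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis (transformer convention)."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mean) / std
    y = gamma.data * xhat + beta.data
    out = Tensor(y, parents=(x, gamma, beta))

    def bwd(g):
        red = tuple(range(g.ndim - 1))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=red))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=red))
        if x.requires_grad:
            gh = g * gamma.data
            gmean = gh.mean(axis=-1, keepdims=True)
            gxhat = (gh * xhat).mean(axis=-1, keepdims=True)
            x.accumulate((gh - gmean - xhat * gxhat) / std)

    out._backward = bwd
    return out


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    x = _wrap(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = Tensor(x.data * keep, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * keep)

    out._backward = bwd
    return out


# -- loss ------------------------------------------------------------------

def softmax_cross_entropy(logits, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy.

    ``logits``: (N, C, H, W); ``target``: integer array (N, H, W) of class ids.
    """
    logits = _wrap(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n, c, h, w = logits.data.shape
    t = np.asarray(target)
    onehot = np.moveaxis(np.eye(c, dtype=p.dtype)[t], -1, 1)
    loss = -(onehot * np.log(np.clip(p, 1e-12, None))).sum(axis=1).mean()
    out = Tensor(np.asarray(loss, dtype=logits.data.dtype), parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            logits.accumulate(g * (p - onehot) / (n * h * w))

    out._backward = bwd
    return out
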