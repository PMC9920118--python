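"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operations the respiration networks need:
1-D convolutions (strided, 'same' padding), zero-stuffing for transposed
convolutions, linear 2x resampling, batch normalisation, dense layers and
the usual pointwise nonlinearities.  Gradients are accumulated by a
topological sweep over the recorded tape.  Correctness of every operation
is pinned by finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "zero_stuff2", "upsample2",
           "avgpool2", "batch_norm", "dense", "dropout", "relu",
           "leaky_relu", "sigmoid", "smooth_l1", "mean_all", "sum_all",
           "square", "sqrt_eps", "reciprocal"]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- graph traversal -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))
        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient g back to `shape` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))
    out._backward = bwd
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * np.where(x.data > 0, 1.0, slope))
    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))
    out._backward = bwd
    return out


def square(x: Tensor) -> Tensor:
    out = Tensor(x.data ** 2, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * 2.0 * x.data)
    out._backward = bwd
    return out


def reciprocal(x: Tensor) -> Tensor:
    r = 1.0 / x.data
    out = Tensor(r, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(-g * r * r)
    out._backward = bwd
    return out


def sqrt_eps(x: Tensor, eps: float = 1e-12) -> Tensor:
    r = np.sqrt(x.data + eps)
    out = Tensor(r, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * 0.5 / r)
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def sum_all(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        if axis is None:
            x._accum(np.broadcast_to(g, x.data.shape).copy()
                     if np.ndim(g) else np.full_like(x.data, g))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            x._accum(np.broadcast_to(gg, x.data.shape).copy())
    out._backward = bwd
    return out


def mean_all(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else x.data.shape[axis]
    return sum_all(x, axis=axis, keepdims=keepdims) * (1.0 / n)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bwd
    return out


def _same_pad(L: int, k: int, stride: int) -> tuple[int, int, int]:
    Lout = -(-L // stride)  # ceil
    total = max((Lout - 1) * stride + k - L, 0)
    return Lout, total // 2, total - total // 2


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """'same'-padded 1-D cross-correlation.  x: (N,C,L), w: (O,C,K), b: (O,)."""
    N, C, L = x.data.shape
    O, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Cw}")
    Lout, pl, pr = _same_pad(L, K, stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    # gather K shifted views: cols[k] has shape (N, C, Lout)
    cols = np.stack([xp[:, :, k:k + stride * Lout:stride] for k in range(K)], axis=2)
    y = np.einsum("nckl,ock->nol", cols, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accum(np.einsum("nol,nckl->ock", g, cols, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k:k + stride * Lout:stride] += np.einsum(
                    "nol,ock->ncl", g, w.data[:, :, k:k + 1], optimize=True)
            x._accum(gxp[:, :, pl:pl + L])
    out._backward = bwd
    return out


def zero_stuff2(x: Tensor) -> Tensor:
    """Insert a zero after every sample (length doubles); the upsampling half
    of a stride-2 transposed convolution."""
    N, C, L = x.data.shape
    y = np.zeros((N, C, 2 * L))
    y[:, :, ::2] = x.data
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[:, :, ::2])
    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Linear 2x upsampling along the last axis.

    out[2i] = x[i]; out[2i+1] = (x[i] + x[i+1]) / 2, clamped at the edge.
    """
    d = x.data
    L = d.shape[-1]
    y = np.empty(d.shape[:-1] + (2 * L,))
    y[..., ::2] = d
    y[..., 1:-1:2] = 0.5 * (d[..., :-1] + d[..., 1:])
    y[..., -1] = d[..., -1]
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = g[..., ::2].copy()
        mid = g[..., 1:-1:2]
        gx[..., :-1] += 0.5 * mid
        gx[..., 1:] += 0.5 * mid
        gx[..., -1] += g[..., -1]
        x._accum(gx)
    out._backward = bwd
    return out


def avgpool2(x: Tensor) -> Tensor:
    """Average pooling with window 2, stride 2 (even input length required)."""
    N, C, L = x.data.shape
    if L % 2:
        raise ValueError("avgpool2 requires even length")
    y = 0.5 * (x.data[:, :, ::2] + x.data[:, :, 1::2])
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros((N, C, L))
            gx[:, :, ::2] = 0.5 * g
            gx[:, :, 1::2] = 0.5 * g
            x._accum(gx)
    out._backward = bwd
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N,F) @ w: (F,O) + b."""
    y = x.data @ w.data + b.data
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        if b.requires_grad:
            b._accum(g.sum(axis=0))
        if w.requires_grad:
            w._accum(x.data.T @ g)
        if x.requires_grad:
            x._accum(g @ w.data.T)
    out._backward = bwd
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running: dict, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation for (N,C,L) inputs.

    `running` carries 'mean' and 'var' arrays updated in-place in training
    mode and used verbatim at inference.
    """
    d = x.data
    if training:
        mu = d.mean(axis=(0, 2))
        var = d.var(axis=(0, 2))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (d - mu[None, :, None]) * inv[None, :, None]
    y = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
    out = Tensor(y, parents=(x, gamma, beta))
    m = d.shape[0] * d.shape[2]

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2)))
        if x.requires_grad:
            gh = g * gamma.data[None, :, None]
            if training:
                t1 = gh.sum(axis=(0, 2), keepdims=True)
                t2 = (gh * xhat).sum(axis=(0, 2), keepdims=True)
                gx = (gh - t1 / m - xhat * t2 / m) * inv[None, :, None]
            else:
                gx = gh * inv[None, :, None]
            x._accum(gx)
    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            active: bool) -> Tensor:
    """Inverted dropout; identity when inactive or p == 0."""
    if not active or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)
    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise Huber-style smooth L1 against a constant target, summed.

    0.5 d^2 for |d| < 1, |d| - 0.5 otherwise; the two branches agree at
    |d| = 1 so the loss is continuous and once-differentiable.
    """
    t = np.asarray(target, dtype=np.float64)
    d = pred.data - t
    a = np.abs(d)
    vals = np.where(a < 1.0, 0.5 * d * d, a - 0.5)
    out = Tensor(vals.sum(), parents=(pred,))

    def bwd(g):
        if pred.requires_grad:
            pred._accum(g * np.where(a < 1.0, d, np.sign(d)))
    out._backward = bwd
    return out
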