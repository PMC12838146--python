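"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The trainable parts of the package (the convolutional encoder, the
anti-cross-attention block, the decorrelation projectors and the spline
classification head) are small enough that a compact tape-based autodiff
engine on ``numpy.ndarray`` values covers them.  The engine supports exactly
the operations those modules need: broadcasting arithmetic, (batched) matrix
products, reductions, softmax / log-softmax, a strided 2-D convolution and a
few elementwise nonlinearities.

Design constraints:

* gradients are never mutated in place -- accumulation always allocates, so a
  backward function may safely return views of its output gradient;
* every operation is differentiable-by-composition, which lets the finite
  difference tests in the suite validate each primitive independently;
* dtype follows the input (float32 for speed in training, float64 in tests).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "cross_entropy",
    "log_softmax",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 1000  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _op(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate ``grad`` (defaults to ones) from this node."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        # iterative topological sort (graphs can be deep for long pipelines)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(np.asarray(g), parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._op(self.data + other.data, (self, other), lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._op(self.data - other.data, (self, other), lambda g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data * other.data,
            (self, other),
            lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data / other.data,
            (self, other),
            lambda g: (g / other.data, -g * self.data / (other.data**2)),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent
        return Tensor._op(
            out_data,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return ga, gb

        return Tensor._op(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def sigmoid(self):
        out_data = expit(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def silu(self):
        """x * sigmoid(x), the smooth default nonlinearity."""
        s = expit(self.data)
        out_data = self.data * s
        return Tensor._op(
            out_data,
            (self,),
            lambda g: (g * (s + self.data * s * (1.0 - s)),),
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._op(np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,))

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._op(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    def maximum(self, value: float):
        """Elementwise max with a scalar; gradient flows where self > value."""
        mask = self.data > value
        return Tensor._op(np.maximum(self.data, value), (self,), lambda g: (g * mask,))

    # -- reductions and reshaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape),)

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._op(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, key):
        shape = self.data.shape

        def backward(g):
            gx = np.zeros(shape, dtype=g.dtype)
            gx[key] = g
            return (gx,)

        return Tensor._op(self.data[key], (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- n-ary / structured operations --------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = tuple(as_tensor(t) for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor._op(y, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        return (g - np.exp(out_data) * g.sum(axis=axis, keepdims=True),)

    return Tensor._op(out_data, (x,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    ls = log_softmax(logits, axis=1)
    return (ls * Tensor(onehot)).sum() * (-1.0 / n)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
               eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalization over ``axes``.

    ``gamma`` / ``beta`` must already be broadcast-shaped (e.g. (1, C) or
    (1, C, 1, 1)).  Returns ``(out, batch_mean, batch_var)`` where the
    statistics are plain arrays for updating running buffers.  Fusing the
    whole normalization into one node keeps the tape short on the large
    feature maps of the encoder.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n = int(np.prod([x.shape[a] for a in axes]))
    if n < 2:
        raise RuntimeError(
            "batch normalization in training mode needs at least 2 values per "
            "channel; use eval mode or a larger batch"
        )
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = gamma.data * xhat + beta.data

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes, keepdims=True)
        dbeta = g.sum(axis=axes, keepdims=True)
        dxhat = g * gamma.data
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std
        return dx, dgamma, dbeta

    return Tensor._op(out, (x, gamma, beta), backward), mu, var


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return cols, ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of NCHW input with OIHW weights."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    b, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(o, c * kh * kw)
    out = cols @ wmat.T + bias.data
    out = out.reshape(b, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        g_cols = g.transpose(0, 2, 3, 1).reshape(b * ho * wo, o)
        g_bias = g_cols.sum(axis=0)
        g_w = (g_cols.T @ cols).reshape(o, c, kh, kw)
        g_colmat = g_cols @ wmat  # (B*Ho*Wo, C*kh*kw)
        g_windows = g_colmat.reshape(b, ho, wo, c, kh, kw)
        gx = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    g_windows[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        return gx, g_w, g_bias

    return Tensor._op(out, (x, weight, bias), backward)
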