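"""A compact reverse-mode automatic differentiation core on numpy arrays.

Scope is deliberately narrow: exactly the operations the networks in this
package use (dense/convolutional affine maps, rectifier/GELU/sigmoid
nonlinearities, softmax, reductions, reshapes, concatenation, slicing and
2x2 max pooling), each with a hand-written vector-Jacobian product.  The
graph is built eagerly; ``Tensor.backward`` runs a topological sweep and
accumulates gradients into ``.grad``.  Correctness is pinned down by
central-difference gradient checks in the test suite.

Shapes follow the usual deep-learning conventions: images are
(N, C, H, W), token sequences are (..., T, d).  Broadcasting in the
elementwise operations mirrors numpy; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that suspends graph construction (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking ndarray (op) Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences --------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- elementwise arithmetic ----------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            self.data * mask, (self,), lambda g: self._accumulate(g * mask)
        )

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            s, (self,), lambda g: self._accumulate(g * s * (1.0 - s))
        )

    def gelu(self):
        """Exact Gaussian-error-linear unit x * Phi(x)."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return Tensor._make(
            x * cdf, (self,), lambda g: self._accumulate(g * (cdf + x * pdf))
        )

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: self._accumulate(g * e))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: self._accumulate(g / self.data)
        )

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor._make(r, (self,), lambda g: self._accumulate(g * 0.5 / r))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            inner = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - inner))

        return Tensor._make(y, (self,), backward)

    # -- reductions and shape ops --------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                grad = np.broadcast_to(g, self.data.shape)
            self._accumulate(np.ascontiguousarray(grad))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape),
            (self,),
            lambda g: self._accumulate(g.reshape(old)),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes),
            (self,),
            lambda g: self._accumulate(g.transpose(inv)),
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2D cross-correlation with stride 1.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,).
    Output spatial size is H + 2*padding - kh + 1 (same for width).
    """
    x, w = Tensor.as_tensor(x), Tensor.as_tensor(w)
    N, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = w.shape
    if Cin != Cin_w:
        raise ValueError(f"input has {Cin} channels, kernel expects {Cin_w}")
    p = padding
    # For small maps a sum over kernel offsets of one large channel-
    # contracting matmul per offset beats im2col (no giant strided copy).
    # Work channels-last so the contraction is over the trailing axis.
    xl = x.data.transpose(0, 2, 3, 1)
    xl = np.pad(xl, ((0, 0), (p, p), (p, p), (0, 0))) if p else np.ascontiguousarray(xl)
    Ho, Wo = xl.shape[1] - kh + 1, xl.shape[2] - kw + 1

    out2d = np.zeros((N * Ho * Wo, Cout))
    for i in range(kh):
        for j in range(kw):
            patch2d = xl[:, i : i + Ho, j : j + Wo, :].reshape(-1, Cin)
            out2d += patch2d @ w.data[:, :, i, j].T
    if b is not None:
        out2d += b.data
    out_data = out2d.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gl2d = g.transpose(0, 2, 3, 1).reshape(-1, Cout)
        if b is not None and b.requires_grad:
            b._accumulate(gl2d.sum(axis=0))
        need_x = x.requires_grad
        dxl = np.zeros_like(xl) if need_x else None
        dw = np.empty_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                if w.requires_grad:
                    patch2d = xl[:, i : i + Ho, j : j + Wo, :].reshape(-1, Cin)
                    dw[:, :, i, j] = gl2d.T @ patch2d
                if need_x:
                    dxl[:, i : i + Ho, j : j + Wo, :] += (
                        gl2d @ w.data[:, :, i, j]
                    ).reshape(N, Ho, Wo, Cin)
        if w.requires_grad:
            w._accumulate(dw)
        if need_x:
            dxp = dxl.transpose(0, 3, 1, 2)
            x._accumulate(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Max pooling with a square window and stride equal to the window size.

    Trailing rows/columns that do not fill a window are discarded
    (floor semantics), so a 9x9 map pools to 4x4 with size=2.
    """
    x = Tensor.as_tensor(x)
    N, C, H, W = x.shape
    Ho, Wo = H // size, W // size
    crop = x.data[:, :, : Ho * size, : Wo * size]
    windows = crop.reshape(N, C, Ho, size, Wo, size).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(windows).reshape(N, C, Ho, Wo, size * size)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dwin = dflat.reshape(N, C, Ho, Wo, size, size).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * size, : Wo * size] = dwin.reshape(N, C, Ho * size, Wo * size)
        x._accumulate(dx)

    return Tensor._make(out_data, (x,), backward)
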