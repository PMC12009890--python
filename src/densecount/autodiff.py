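"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small dynamic-graph engine: every operation returns a new
:class:`Tensor` that remembers its parents and a closure that propagates the
upstream gradient to them.  Only the primitives needed by the counting models
are provided (broadcast arithmetic, batched matmul, reductions, reshaping,
gather/embed, stride-1 dilated convolution, 2x2 max pooling and the usual
pointwise nonlinearities).  Gradients are accumulated in ``Tensor.grad`` as
plain numpy arrays.

The engine is validated against central finite differences in the test suite;
any new primitive must come with a gradient check.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "embed",
    "gelu",
    "matmul",
    "maxpool2x2",
    "relu",
    "sigmoid",
    "softmax",
]


def _as_array(value, dtype=None) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    if arr.dtype.kind in "iub":
        arr = arr.astype(np.float64)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(grad):
            self._accumulate(_unbroadcast(grad, self.shape))
            other._accumulate(_unbroadcast(grad, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            self._accumulate(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(grad):
            self._accumulate(_unbroadcast(grad * other.data, self.shape))
            other._accumulate(_unbroadcast(grad * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(grad):
            self._accumulate(_unbroadcast(grad / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-grad * self.data / (other.data**2), other.shape)
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(grad):
            self._accumulate(grad * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            out = out_data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                out = np.expand_dims(out_data, axis)
            mask = self.data == out
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accumulate(mask * (g / counts))

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.shape

        def backward(grad):
            self._accumulate(grad.reshape(in_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad):
            self._accumulate(grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(grad):
            g = np.zeros_like(self.data)
            np.add.at(g, idx, grad)
            self._accumulate(g)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the two trailing spatial axes of an (..., H, W) tensor."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, pad + self.shape[-2]), slice(pad, pad + self.shape[-1]))

        def backward(grad):
            self._accumulate(grad[sl])

        return Tensor._make(out_data, (self,), backward)

    def roll(self, shift, axis):
        def backward(grad):
            self._accumulate(np.roll(grad, tuple(-s for s in shift), axis))

        return Tensor._make(np.roll(self.data, shift, axis), (self,), backward)

    # -- pointwise nonlinearities --------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad):
            self._accumulate(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = _special.expit(self.data)

        def backward(grad):
            self._accumulate(grad * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            self._accumulate(grad * out_data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(grad):
            self._accumulate(grad * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + _special.erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def backward(grad):
            self._accumulate(grad * (cdf + x * pdf))

        return Tensor._make(x * cdf, (self,), backward)

    # -- backprop -------------------------------------------------------------
    def backward(self, grad=None) -> None:
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self:
                    node.grad = None  # free intermediate gradients


# -- free functions -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def gelu(x: Tensor) -> Tensor:
    return x.gelu()


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    out_data = np.matmul(a.data, b.data)

    def backward(grad):
        ga = np.matmul(grad, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), grad)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(out_data, (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def embed(x: Tensor, shape: tuple, offset: tuple) -> Tensor:
    """Place ``x`` inside a zero array of ``shape`` at ``offset`` (trailing axes)."""
    out_data = np.zeros(shape, dtype=x.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, x.shape))
    out_data[sl] = x.data

    def backward(grad):
        x._accumulate(grad[sl])

    return Tensor._make(out_data, (x,), backward)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """Stride-1 2-D cross-correlation with zero padding and dilation.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,) or None.
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    p, d = int(padding), int(dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    hout = h + 2 * p - (kh - 1) * d
    wout = wd + 2 * p - (kw - 1) * d
    if hout <= 0 or wout <= 0:
        raise ValueError("kernel footprint larger than padded input")
    out_data = np.zeros((n, o, hout, wout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * d : i * d + hout, j * d : j * d + wout]
            out_data += np.tensordot(w.data[:, :, i, j], xs, axes=([1], [1])).transpose(
                1, 0, 2, 3
            )
    if b is not None:
        out_data += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                if gw is not None:
                    xs = xp[:, :, i * d : i * d + hout, j * d : j * d + wout]
                    gw[:, :, i, j] = np.tensordot(grad, xs, axes=([0, 2, 3], [0, 2, 3]))
                if x.requires_grad:
                    gxp[:, :, i * d : i * d + hout, j * d : j * d + wout] += (
                        np.tensordot(w.data[:, :, i, j], grad, axes=([0], [1]))
                    ).transpose(1, 0, 2, 3)
        if x.requires_grad:
            x._accumulate(gxp[:, :, p : p + h, p : p + wd])
        if gw is not None:
            w._accumulate(gw)
        if b is not None:
            b._accumulate(grad.sum(axis=(0, 2, 3)))

    return Tensor._make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 on an (N, C, H, W) tensor (H, W even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial sides")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = blocks.max(axis=(3, 5))

    def backward(grad):
        mask = blocks == out_data[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None] / counts)
        x._accumulate(g.reshape(n, c, h, w))

    return Tensor._make(out_data, (x,), backward)
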