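"""Reverse-mode automatic differentiation on NumPy arrays.

A compact tape-based autodiff core: :class:`Tensor` wraps an ndarray and
records a backward closure per operation. It supports exactly the operator
set the convolutional generators/discriminators and their losses need
(broadcast arithmetic, reductions, reshaping, slicing, concatenation,
element-wise nonlinearities). Convolution, pooling and normalization live in
:mod:`palocal.grad.functional` / :mod:`palocal.grad.layers`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype != np.float32:  # float32 preserved for speed, rest promoted
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (scalar unless `grad` is given) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if not node.requires_grad:
                node.grad = None  # free intermediates

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, keeps dtype
            out = Tensor(self.data + other, _parents=(self,))
            out._backward = lambda g: self._accum(_unbroadcast(g, self.data.shape))
            return out
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, _parents=(self,))
            out._backward = lambda g: self._accum(_unbroadcast(g * other, self.data.shape))
            return out
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, expo: float):
        out = Tensor(self.data**expo, _parents=(self,))
        out._backward = lambda g: self._accum(g * expo * self.data ** (expo - 1))
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def sigmoid(self):
        # exp overflow for very negative inputs saturates to inf -> s == 0.0,
        # which is the correct limit; silence the spurious warning.
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(self.data > 0, 1.0, slope))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape manipulation ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            fancy = any(
                isinstance(i, (np.ndarray, list)) for i in (idx if isinstance(idx, tuple) else (idx,))
            )
            if fancy:
                np.add.at(full, idx, g)  # fancy indexing may repeat elements
            else:
                full[idx] += g
            self._accum(full)

        out._backward = bw
        return out

    def pad(self, pad_width, value: float = 0.0):
        out = Tensor(np.pad(self.data, pad_width, constant_values=value), _parents=(self,))
        sl = tuple(slice(l, l + s) for (l, _), s in zip(pad_width, self.data.shape))
        out._backward = lambda g: self._accum(g[sl])
        return out

    def dilate(self, stride: tuple[int, ...]):
        """Insert stride-1 zeros between elements of the trailing spatial axes.

        Used to realize transposed (fractionally strided) convolution as
        zero-insertion followed by an ordinary convolution.
        """
        d = len(stride)
        lead = self.data.shape[: self.ndim - d]
        sp = self.data.shape[self.ndim - d:]
        new_sp = tuple((n - 1) * s + 1 for n, s in zip(sp, stride))
        data = np.zeros(lead + new_sp, dtype=self.data.dtype)
        sl = (slice(None),) * len(lead) + tuple(slice(None, None, s) for s in stride)
        data[sl] = self.data
        out = Tensor(data, _parents=(self,))
        out._backward = lambda g: self._accum(g[sl])
        return out


def concatenate(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, routing gradients back by slices."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bw
    return out
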