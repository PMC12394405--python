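"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ndarray and
remembers how to push gradients to its parents.  The operation set is
exactly what the assessment network needs — broadcast arithmetic, matmul,
a strided 1-D convolution over time, reductions, elementwise
nonlinearities, shape ops and concatenation.  Gradients are accumulated in
``float64`` and the whole engine is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "conv1d", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (evaluation mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autograd engine -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
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

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent
        if not (self.requires_grad and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        if not (req and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        src_shape = self.shape

        def backward(g):
            self._accumulate(g.reshape(src_shape))

        out._backward = backward
        return out

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        if not (self.requires_grad and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out_data = self.data[key]
        if not (self.requires_grad and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- elementwise nonlinearities -------------------------------------
    def _unary(self, out_data, dfn):
        if not (self.requires_grad and _grad_enabled):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            self._accumulate(g * dfn(out_data))

        out._backward = backward
        return out

    def exp(self):
        y = np.exp(self.data)
        return self._unary(y, lambda out: out)

    def log(self):
        return self._unary(np.log(self.data), lambda _: 1.0 / self.data)

    def tanh(self):
        y = np.tanh(self.data)
        return self._unary(y, lambda out: 1.0 - out**2)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, lambda out: out * (1.0 - out))

    def relu(self):
        y = np.maximum(self.data, 0.0)
        return self._unary(y, lambda _: (self.data > 0).astype(np.float64))

    def abs(self):
        return self._unary(np.abs(self.data), lambda _: np.sign(self.data))

    def sqrt(self):
        return self**0.5

    # ---- softmax family --------------------------------------------------
    def softmax(self, axis: int = -1):
        # shifting by the (constant) max leaves both value and gradient intact
        shift = self - self.data.max(axis=axis, keepdims=True)
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shift = self - self.data.max(axis=axis, keepdims=True)
        lse = shift.exp().sum(axis=axis, keepdims=True).log()
        return shift - lse


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _grad_enabled):
        return Tensor(out_data)
    out = Tensor(out_data, True, tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def conv1d(
    x: Tensor, w: Tensor, bias: Tensor | None = None, stride: int = 1,
    pad: tuple[int, int] = (0, 0),
) -> Tensor:
    """Strided 1-D convolution over the last axis.

    ``x`` is (B, C_in, T), ``w`` is (C_out, C_in, K); zero padding
    ``pad = (left, right)`` is applied before the strided window.
    """
    B, C, T = x.shape
    O, C2, K = w.shape
    if C != C2:
        raise ValueError(f"conv1d channel mismatch: input {C}, weight {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), pad), mode="constant")
    Tp = xp.shape[2]
    T_out = (Tp - K) // stride + 1
    s0, s1, s2 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, T_out, K), strides=(s0, s1, s2 * stride, s2),
        writeable=False,
    )
    out_data = np.einsum("bctk,ock->bot", windows, w.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]
    req = x.requires_grad or w.requires_grad or (
        bias is not None and bias.requires_grad
    )
    if not (req and _grad_enabled):
        return Tensor(out_data)
    parents = (x, w) if bias is None else (x, w, bias)
    out = Tensor(out_data, True, parents)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("bctk,bot->ock", windows, g, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            gx_full = np.einsum("bot,ock->bctk", g, w.data, optimize=True)
            for k in range(K):
                gxp[:, :, k : k + stride * T_out : stride] += gx_full[:, :, :, k]
            left, right = pad
            gx = gxp[:, :, left : Tp - right] if right else gxp[:, :, left:]
            x._accumulate(gx)

    out._backward = backward
    return out
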