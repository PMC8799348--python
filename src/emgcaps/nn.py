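"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the capsule
network needs: broadcasting arithmetic, relu/exp/sqrt, strided valid/padded
2-D convolution (via strided views), two-operand einsum, softmax, reshape /
transpose / concatenate, and reductions — plus an Adam optimizer.  All
computation is float64, which keeps finite-difference gradient checks tight.

Gradients propagate through every operation; ``Tensor(..., requires_grad=
True)`` marks leaves (parameters).  ``backward()`` on a scalar seeds the
reverse sweep in topological order.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Adam", "conv2d", "einsum2", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    # -- graph bookkeeping --------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if parent.requires_grad or parent._parents:
                        key = id(parent)
                        if key in grads:
                            grads[key] = grads[key] + pg
                        else:
                            grads[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape helpers ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out_data = self.data.reshape(*shape)
        return Tensor._make(
            out_data, (self,), lambda g: [(self, g.reshape(old))]
        )

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes),
            (self,),
            lambda g: [(self, g.transpose(*inv))],
        )

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g / other.data, self.data.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
            ],
        )

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) / self

    def __pow__(self, p: float) -> "Tensor":
        return Tensor._make(
            self.data**p,
            (self,),
            lambda g: [(self, g * p * self.data ** (p - 1))],
        )

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: [(self, g * out_data)])

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)
        return Tensor._make(
            out_data, (self,), lambda g: [(self, g * 0.5 / out_data)]
        )

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), (self,), lambda g: [(self, g * mask)]
        )

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: [(self, g * out_data * (1.0 - out_data))]
        )

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo
        return Tensor._make(
            np.maximum(self.data, lo), (self,), lambda g: [(self, g * mask)]
        )

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.data.shape).copy())]
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(gg, self.data.shape).copy())]

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def norm(self, axis: int = -1, keepdims: bool = False, floor: float = 1e-12) -> "Tensor":
        """Euclidean norm along ``axis``, floored near ``floor``.

        Computed as ``sqrt(sum(x^2) + floor^2)`` so the gradient stays finite
        at the zero vector; the perturbation is ~1e-24 and far below any
        tolerance used here.
        """
        return ((self**2).sum(axis=axis, keepdims=keepdims) + floor**2).sqrt()

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return list(zip(tensors, pieces))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return [(x, y * (g - dot))]

    return Tensor._make(y, (x,), backward)


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """``np.einsum`` for two operands, differentiable.

    Every index of each operand must appear in the output or in the other
    operand (no indices summed within a single operand) — true of all the
    contractions the capsule network uses.
    """
    lhs, out_sub = subscripts.split("->")
    a_sub, b_sub = lhs.split(",")
    out_data = np.einsum(subscripts, a.data, b.data)

    def backward(g):
        ga = np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data)
        gb = np.einsum(f"{a_sub},{out_sub}->{b_sub}", a.data, g)
        return [(a, ga), (b, gb)]

    return Tensor._make(out_data, (a, b), backward)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: tuple[int, int] = (1, 1),
    padding: tuple[int, int] = (0, 0),
) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), w (O,C,kh,kw) -> (N,O,Ho,Wo)."""
    sh, sw = stride
    ph, pw = padding
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    kh, kw = w.data.shape[2], w.data.shape[3]
    view = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    out_data = np.einsum("nchwij,ocij->nohw", view, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        grads = []
        gw = np.einsum("nchwij,nohw->ocij", view, g, optimize=True)
        grads.append((w, gw))
        gx_pad = np.zeros_like(xd)
        Ho, Wo = g.shape[2], g.shape[3]
        for i in range(kh):
            for j in range(kw):
                # contribution of kernel tap (i, j) scattered onto the input
                patch = np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
                gx_pad[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += patch
        gx = gx_pad[:, :, ph : gx_pad.shape[2] - ph or None, pw : gx_pad.shape[3] - pw or None]
        grads.append((x, gx))
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
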