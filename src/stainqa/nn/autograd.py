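"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the package's small networks and composite
losses need: broadcasting arithmetic, matmul (including batched), elementwise
nonlinearities, reductions, slicing/reshaping, 2-D convolution via im2col, and
nearest-neighbour upsampling.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward` over a topologically sorted tape.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

LOG10 = np.log(10.0)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    # -- elementwise -------------------------------------------------------
    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def log10(self):
        return self.log() / LOG10

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = bwd
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                inside = (self.data >= lo) & (self.data <= hi)
                self._accumulate(g * inside)

        out._backward = bwd
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes of a (..., H, W) tensor."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    out = Tensor(np.pad(x.data, widths), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            x._accumulate(g[sl])

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation): x (B,C,H,W), w (O,C,kh,kw)."""
    x = as_tensor(x)
    w = as_tensor(w)
    xp = pad2d(x, pad)
    B, C, H, W = xp.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(xp.data, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]                       # B,C,Ho,Wo,kh,kw
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
    wflat = w.data.reshape(O, -1)
    out_data = cols @ wflat.T                                    # B,Ho*Wo,O
    out_data = out_data.transpose(0, 2, 1).reshape(B, O, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    parents = (xp, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        gflat = g.reshape(B, O, Ho * Wo).transpose(0, 2, 1)      # B,Ho*Wo,O
        if w.requires_grad:
            gw = np.einsum("bno,bnk->ok", gflat, cols).reshape(w.shape)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            gcols = gflat @ wflat                                # B,Ho*Wo,C*kh*kw
            gcols = gcols.reshape(B, Ho, Wo, C, kh, kw)
            gx = np.zeros((B, C, H, W))
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            xp._accumulate(gx)

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of a (B,C,H,W) tensor."""
    x = as_tensor(x)
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            B, C, H2, W2 = g.shape
            gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gx)

    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)
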