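"""A compact reverse-mode automatic-differentiation engine over numpy.

The registration cascade and the CycleGAN in this package are small enough
that a hand-rolled tape-based autograd over float32 numpy arrays is both fast
enough on one CPU core and fully deterministic. Convolutions are evaluated as
per-kernel-offset shifted GEMMs, which benchmarks several times faster than
im2col at the volume sizes used here.

Conventions
-----------
* 3D feature maps are ``(C, D, H, W)`` (no batch; the 3D nets run batch 1).
* 2D feature maps are ``(B, C, H, W)``.
* ``Tensor`` wraps a float32 array; ``backward()`` runs reverse topological
  accumulation from a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # ------------------------------------------------------------- arithmetic
    # Python scalars get a fast path: mixing them into numpy arithmetic keeps
    # the array dtype (wrapping them as 0-d float64 arrays would promote the
    # whole graph to float64).
    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, self.requires_grad, (self,))
            out._backward = lambda g: self._accum(g)
            return out
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
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
            out = Tensor(self.data * other, self.requires_grad, (self,))
            out._backward = lambda g: self._accum(g * other)
            return out
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def square(self):
        return self * self

    def sqrt(self):
        od = np.sqrt(self.data)
        out = Tensor(od, self.requires_grad, (self,))
        # capture the data array, not ``out``: a self-referencing closure
        # would create a reference cycle and delay freeing whole graphs
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(od, 1e-12))
        return out

    def exp(self):
        od = np.exp(self.data)
        out = Tensor(od, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * od)
        return out

    def tanh(self):
        od = np.tanh(self.data)
        out = Tensor(od, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - od**2))
        return out

    def log(self):
        od = np.log(self.data)
        out = Tensor(od, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def atanh(self):
        """Inverse hyperbolic tangent; callers should clip away from ±1."""
        x = self
        return ((x + 1.0) / (1.0 - x)).log() * 0.5

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def leaky_relu(self, alpha: float = 0.2):
        mask = self.data >= 0
        out = Tensor(np.where(mask, self.data, alpha * self.data), self.requires_grad, (self,))
        scale = np.where(mask, 1.0, alpha).astype(self.data.dtype)
        out._backward = lambda g: self._accum(g * scale)
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            gi = np.zeros_like(self.data)
            np.put_along_axis(gi, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gi)

        out._backward = bw
        return out

    # ------------------------------------------------------------- structural
    def shift(self, axis: int, offset: int):
        """Shift along ``axis`` by ``offset`` with edge replication.

        ``out[i] = in[clip(i + offset)]``; the backward pass scatter-adds into
        the clipped source positions, so boundary rows accumulate.
        """
        n = self.data.shape[axis]
        idx = np.clip(np.arange(n) + offset, 0, n - 1)
        out = Tensor(np.take(self.data, idx, axis=axis), self.requires_grad, (self,))

        def bw(g):
            gi = np.zeros_like(self.data)
            sl: list = [slice(None)] * self.data.ndim
            # interior: one-to-one mapping, handled with slice adds (fast path)
            if offset >= 0:
                lo, hi = 0, n - offset
                src = slice(offset, n)
            else:
                lo, hi = -offset, n
                src = slice(0, n + offset)
            sl[axis] = src
            gsl: list = [slice(None)] * self.data.ndim
            gsl[axis] = slice(lo, hi)
            gi[tuple(sl)] += g[tuple(gsl)]
            # clipped edge: all out-of-range reads hit the boundary voxel
            if offset > 0:
                esl: list = [slice(None)] * self.data.ndim
                esl[axis] = slice(n - offset, n)
                bsl: list = [slice(None)] * self.data.ndim
                bsl[axis] = slice(n - 1, n)
                gi[tuple(bsl)] += g[tuple(esl)].sum(axis=axis, keepdims=True)
            elif offset < 0:
                esl = [slice(None)] * self.data.ndim
                esl[axis] = slice(0, -offset)
                bsl = [slice(None)] * self.data.ndim
                bsl[axis] = slice(0, 1)
                gi[tuple(bsl)] += g[tuple(esl)].sum(axis=axis, keepdims=True)
            self._accum(gi)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def repeat_axis(self, axis: int, factor: int):
        """Nearest-neighbor upsampling: repeat each element ``factor`` times."""
        out = Tensor(np.repeat(self.data, factor, axis=axis), self.requires_grad, (self,))

        def bw(g):
            n = self.data.shape[axis]
            gs = g.reshape(
                g.shape[:axis] + (n, factor) + g.shape[axis + 1 :]
            ).sum(axis=axis + 1)
            self._accum(gs)

        out._backward = bw
        return out

    def avg_pool(self, axis: int, factor: int):
        """Block-average downsampling along ``axis`` (size must divide)."""
        n = self.data.shape[axis]
        if n % factor:
            raise ValueError(f"axis size {n} not divisible by {factor}")
        newshape = self.data.shape[:axis] + (n // factor, factor) + self.data.shape[axis + 1 :]
        out = Tensor(self.data.reshape(newshape).mean(axis=axis + 1), self.requires_grad, (self,))

        def bw(g):
            self._accum(
                np.repeat(g / factor, factor, axis=axis).reshape(self.data.shape)
            )

        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl: list = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad or t._prev:
                t._accum(g[tuple(sl)])
            start += s

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad or t._prev:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out
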