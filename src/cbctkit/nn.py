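"""Convolutional layers, residual blocks and the Adam optimizer used by the
registration cascade (3D) and the CycleGAN (2D).

Convolutions are computed as one GEMM per kernel offset on shifted views,
with 'same' zero padding. 3D feature maps are ``(C, D, H, W)``; 2D feature
maps are ``(B, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


# --------------------------------------------------------------------- conv3d
def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    C, D, H, W = x.data.shape
    O, Cw, kd, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    s = stride
    oD = (D + 2 * pd - kd) // s + 1
    oH = (H + 2 * ph - kh) // s + 1
    oW = (W + 2 * pw - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    N = oD * oH * oW
    y = np.zeros((O, N), dtype=x.data.dtype)
    wf = w.data.reshape(O, C, -1)

    def _slices(i, j, k):
        return (
            slice(None),
            slice(i, i + s * (oD - 1) + 1, s),
            slice(j, j + s * (oH - 1) + 1, s),
            slice(k, k + s * (oW - 1) + 1, s),
        )

    idx = 0
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                y += wf[:, :, idx] @ xp[_slices(i, j, k)].reshape(C, N)
                idx += 1
    if b is not None:
        y += b.data[:, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(O, oD, oH, oW), True, prev)

    def bw(g):
        gy = g.reshape(O, N)
        need_x = x.requires_grad or x._prev
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.empty((O, C, kd * kh * kw), dtype=x.data.dtype) if w.requires_grad else None
        idx2 = 0
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    sl = _slices(i, j, k)
                    if gw is not None:
                        gw[:, :, idx2] = gy @ xp[sl].reshape(C, N).T
                    if need_x:
                        gxp[sl] += (wf[:, :, idx2].T @ gy).reshape(C, oD, oH, oW)
                    idx2 += 1
        if gw is not None:
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=1))
        if need_x:
            x._accum(gxp[:, pd : pd + D, ph : ph + H, pw : pw + W])

    out._backward = bw
    return out


# --------------------------------------------------------------------- conv2d
def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    ph, pw = kh // 2, kw // 2
    s = stride
    oH = (H + 2 * ph - kh) // s + 1
    oW = (W + 2 * pw - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # channel-major layout so each shifted slice flattens to (C, B*oH*oW)
    xpc = np.ascontiguousarray(xp.transpose(1, 0, 2, 3))
    N = B * oH * oW
    y = np.zeros((O, N), dtype=x.data.dtype)
    wf = w.data.reshape(O, C, -1)

    def _slices(j, k):
        return (
            slice(None),
            slice(None),
            slice(j, j + s * (oH - 1) + 1, s),
            slice(k, k + s * (oW - 1) + 1, s),
        )

    idx = 0
    for j in range(kh):
        for k in range(kw):
            y += wf[:, :, idx] @ xpc[_slices(j, k)].reshape(C, N)
            idx += 1
    if b is not None:
        y += b.data[:, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(O, B, oH, oW).transpose(1, 0, 2, 3), True, prev)

    def bw(g):
        gy = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(O, N)
        need_x = x.requires_grad or x._prev
        gxpc = np.zeros_like(xpc) if need_x else None
        gw = np.empty((O, C, kh * kw), dtype=x.data.dtype) if w.requires_grad else None
        idx2 = 0
        for j in range(kh):
            for k in range(kw):
                sl = _slices(j, k)
                if gw is not None:
                    gw[:, :, idx2] = gy @ xpc[sl].reshape(C, N).T
                if need_x:
                    gxpc[sl] += (wf[:, :, idx2].T @ gy).reshape(C, B, oH, oW)
                idx2 += 1
        if gw is not None:
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=1))
        if need_x:
            gx = gxpc.transpose(1, 0, 2, 3)[:, :, ph : ph + H, pw : pw + W]
            x._accum(np.ascontiguousarray(gx))

    out._backward = bw
    return out


# --------------------------------------------------------------------- layers
class Module:
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, zero_init=False):
        shape = (c_out, c_in, k, k, k)
        fan = c_in * k**3
        self.w = Tensor(np.zeros(shape, np.float32) if zero_init else _he_init(rng, shape, fan),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, self.stride)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, zero_init=False):
        shape = (c_out, c_in, k, k)
        fan = c_in * k**2
        self.w = Tensor(np.zeros(shape, np.float32) if zero_init else _he_init(rng, shape, fan),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c, eps=1e-5):
        self.g = Tensor(np.ones((1, c, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.beta


class ResBlock3d(Module):
    def __init__(self, rng, c):
        self.c1 = Conv3d(rng, c, c)
        self.c2 = Conv3d(rng, c, c)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c1(x).leaky_relu(0.2)
        return x + self.c2(h)


class ResBlock2d(Module):
    def __init__(self, rng, c):
        self.c1 = Conv2d(rng, c, c)
        self.n1 = InstanceNorm2d(c)
        self.c2 = Conv2d(rng, c, c)
        self.n2 = InstanceNorm2d(c)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.n1(self.c1(x)).relu()
        return x + self.n2(self.c2(h))


def upsample2(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    for ax in axes:
        x = x.repeat_axis(ax, 2)
    return x


def unet_concat(a: Tensor, b: Tensor) -> Tensor:
    return concat([a, b], axis=1)


# ---------------------------------------------------------------------- optim
class Adam:
    """Adam with optional global-norm gradient clipping (a cheap, fully
    deterministic stabilizer for the instance-fit registration runs)."""

    def __init__(self, params: list[Tensor], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 grad_clip: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.grad_clip = grad_clip
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.grad_clip is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.grad_clip:
                scale = self.grad_clip / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
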