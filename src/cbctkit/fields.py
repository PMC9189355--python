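"""Dense displacement fields: warping, composition, resizing, Jacobians.

A field ``u`` has shape ``(nz, ny, nx, 3)`` with components ``(dz, dy, dx)``
in voxel units on the fixed-image grid, and the warp convention

    ``out(x) = in(x + u(x))``

i.e. the field maps fixed-grid coordinates into moving-image space.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .core_io import AIR_HU


def _check_field(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[3] != 3:
        raise ValueError(f"field must be (nz,ny,nx,3), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    return field


def _grid_coords(shape) -> list[np.ndarray]:
    return list(np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij"))


def warp(vol: np.ndarray, field: np.ndarray, mode: str = "linear", fill: float = AIR_HU) -> np.ndarray:
    """Resample ``vol`` at ``x + u(x)``; out-of-bounds reads return ``fill``."""
    field = _check_field(field)
    vol = np.asarray(vol)
    if vol.shape != field.shape[:3]:
        raise ValueError(f"volume {vol.shape} does not match field grid {field.shape[:3]}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    coords = _grid_coords(vol.shape)
    for d in range(3):
        coords[d] = coords[d] + field[..., d]
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        vol.astype(np.float32), coords, order=order, mode="constant", cval=fill
    )
    if mode == "nearest" and np.issubdtype(np.asarray(vol).dtype, np.integer):
        return np.rint(out).astype(vol.dtype)
    return out


def compose(f_outer: np.ndarray, f_inner: np.ndarray) -> np.ndarray:
    """Field of the sequential warp ``warp(warp(I, f_outer), f_inner)``.

    ``(f_outer ∘ f_inner)(x) = f_inner(x) + f_outer(x + f_inner(x))`` with
    linear interpolation (edge clamp) when sampling the outer field.
    """
    f_outer = _check_field(f_outer)
    f_inner = _check_field(f_inner)
    if f_outer.shape != f_inner.shape:
        raise ValueError(f"shape mismatch: {f_outer.shape} vs {f_inner.shape}")
    coords = _grid_coords(f_outer.shape[:3])
    for d in range(3):
        coords[d] = coords[d] + f_inner[..., d]
    out = np.empty_like(f_inner)
    for d in range(3):
        out[..., d] = f_inner[..., d] + ndimage.map_coordinates(
            f_outer[..., d], coords, order=1, mode="nearest"
        )
    return out


def resize_field(field: np.ndarray, target_shape) -> np.ndarray:
    """Resize a field to a new grid, rescaling displacements to new voxel units."""
    field = _check_field(field)
    src = field.shape[:3]
    out = np.empty(tuple(target_shape) + (3,), dtype=np.float32)
    factors = [t / s for t, s in zip(target_shape, src)]
    for d in range(3):
        comp = ndimage.zoom(field[..., d], factors, order=1, mode="nearest", grid_mode=True)
        # zoom can be off by one voxel on odd sizes; guard with crop/pad
        comp = comp[: target_shape[0], : target_shape[1], : target_shape[2]]
        out[..., d] = comp * factors[d]
    return out


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Determinant of the discrete Jacobian of ``x + u(x)`` (central diffs)."""
    field = _check_field(field)
    grads = np.empty(field.shape[:3] + (3, 3), dtype=np.float32)
    for d in range(3):  # component
        for a in range(3):  # derivative axis
            grads[..., d, a] = np.gradient(field[..., d], axis=a)
    jac = grads + np.eye(3, dtype=np.float32)
    return np.linalg.det(jac)


def downsample_volume(vol: np.ndarray, factor: int) -> np.ndarray:
    """Block-average pooling by ``factor`` on every axis (must divide)."""
    z, y, x = vol.shape
    if z % factor or y % factor or x % factor:
        raise ValueError(f"shape {vol.shape} not divisible by {factor}")
    return (
        vol.reshape(z // factor, factor, y // factor, factor, x // factor, factor)
        .mean(axis=(1, 3, 5))
        .astype(np.float32)
    )


# ----------------------------------------------------------- differentiable warp
def warp_t(moving: np.ndarray, field: Tensor, fill: float | None = None) -> Tensor:
    """Differentiable trilinear warp of a constant 3D volume by a field tensor.

    ``field`` has shape ``(3, D, H, W)``. Sample positions are clamped to the
    volume bounds (replicate behavior), which keeps the objective smooth at
    the borders during optimization; the non-differentiable :func:`warp` with
    constant fill is used for final outputs.
    """
    moving = np.asarray(moving, dtype=np.float32)
    D, H, W = moving.shape
    if field.data.shape != (3, D, H, W):
        raise ValueError(f"field shape {field.data.shape} != (3,{D},{H},{W})")
    base = np.stack(_grid_coords((D, H, W)), axis=0)
    pos = base + field.data
    eps = 1e-4
    lim = np.array([D - 1, H - 1, W - 1], dtype=np.float32).reshape(3, 1, 1, 1)
    clamped = np.clip(pos, 0.0, lim - eps)
    inside = (pos >= 0.0) & (pos <= lim)  # derivative is zero where clamped
    i0 = clamped.astype(np.int64)
    f = clamped - i0
    z0, y0, x0 = i0
    fz, fy, fx = f
    flat = moving.ravel()
    sHW, sW = H * W, W

    def gather(dz, dy, dx):
        return flat[(z0 + dz) * sHW + (y0 + dy) * sW + (x0 + dx)]

    c000, c001 = gather(0, 0, 0), gather(0, 0, 1)
    c010, c011 = gather(0, 1, 0), gather(0, 1, 1)
    c100, c101 = gather(1, 0, 0), gather(1, 0, 1)
    c110, c111 = gather(1, 1, 0), gather(1, 1, 1)

    c00 = c000 * (1 - fx) + c001 * fx
    c01 = c010 * (1 - fx) + c011 * fx
    c10 = c100 * (1 - fx) + c101 * fx
    c11 = c110 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    out_data = c0 * (1 - fz) + c1 * fz

    out = Tensor(out_data, True, (field,))

    def bw(g):
        dz_ = (c1 - c0) * inside[0]
        dy_ = ((c01 - c00) * (1 - fz) + (c11 - c10) * fz) * inside[1]
        dx_ = (
            (c001 - c000) * (1 - fy) * (1 - fz)
            + (c011 - c010) * fy * (1 - fz)
            + (c101 - c100) * (1 - fy) * fz
            + (c111 - c110) * fy * fz
        ) * inside[2]
        field._accum(np.stack([g * dz_, g * dy_, g * dx_], axis=0).astype(field.data.dtype))

    out._backward = bw
    return out
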