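"""Modality-independent neighborhood descriptor (MIND) and its L1 loss.

MIND represents each voxel by a vector of variance-normalized patch
self-dissimilarities to a small set of neighbors; because the local variance
normalization cancels affine intensity maps, the descriptor — and hence the
loss — is nearly invariant to the intensity differences between CT and CBCT.
Two implementations are provided: a plain-numpy one used for evaluation and
fixed-image precomputation, and an autodiff one used inside training losses.
Both share the same construction:

* patch dissimilarity ``Dp(x, o)``: Gaussian-weighted SSD between the patch
  at ``x`` and the patch at ``x + o`` (replicate padding at the borders);
* variance estimate ``V(x)``: mean of ``Dp`` over the offsets, floored at a
  small fraction of its global mean;
* channels ``exp(-Dp/V)``, divided by the per-voxel channel maximum so the
  largest channel equals 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, stack

_OFFSETS_3D = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
_OFFSETS_2D = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclasses.dataclass
class MINDParams:
    """Descriptor hyperparameters.

    offsets
        Neighbor offsets in voxels; ``None`` selects the six (3D) or four
        (2D) axial unit offsets.
    patch_radius_inplane / patch_radius_z
        Half-width of the weighting patch in voxels. The through-plane radius
        defaults to 0 because slices are several times thicker than pixels.
    sigma_patch
        Standard deviation (voxels) of the Gaussian patch weights.
    eps_frac
        Variance floor as a fraction of the volume-mean variance. Because the
        per-voxel normalization is scale-invariant, independent noise in two
        otherwise matching images produces O(1) descriptor mismatch across
        homogeneous tissue unless the floor is a substantial fraction of the
        mean; the default suppresses this while leaving genuine edges (whose
        dissimilarities sit far above the mean) intact.
    """

    offsets: tuple | None = None
    patch_radius_inplane: int = 1
    patch_radius_z: int = 0
    sigma_patch: float = 0.8
    eps_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.offsets is not None and len(self.offsets) < 2:
            raise ValueError("MIND needs at least 2 offsets")
        if self.patch_radius_inplane < 0 or self.patch_radius_z < 0:
            raise ValueError("patch radii must be non-negative")
        if self.eps_frac <= 0:
            raise ValueError("eps_frac must be positive")

    def resolved_offsets(self, ndim_spatial: int) -> tuple:
        if self.offsets is not None:
            return tuple(tuple(o) for o in self.offsets)
        return _OFFSETS_3D if ndim_spatial == 3 else _OFFSETS_2D

    def taps(self) -> np.ndarray:
        r = self.patch_radius_inplane
        if r == 0:
            return np.array([1.0], dtype=np.float32)
        d = np.arange(-r, r + 1, dtype=np.float64)
        w = np.exp(-(d**2) / (2 * self.sigma_patch**2))
        return (w / w.sum()).astype(np.float32)


# ------------------------------------------------------------------ numpy path
def _shift_np(x: np.ndarray, offset, spatial_axes) -> np.ndarray:
    out = x
    for ax, o in zip(spatial_axes, offset):
        if o == 0:
            continue
        idx = np.clip(np.arange(x.shape[ax]) + o, 0, x.shape[ax] - 1)
        out = np.take(out, idx, axis=ax)
    return out


def _smooth_np(x: np.ndarray, taps: np.ndarray, axes) -> np.ndarray:
    for ax in axes:
        if len(taps) > 1:
            x = ndimage.correlate1d(x, taps, axis=ax, mode="nearest")
    return x


def mind_descriptor(vol, params: MINDParams | None = None, spatial_axes: tuple | None = None) -> np.ndarray:
    """Descriptor field; returns ``(K, *vol.shape)``.

    ``spatial_axes`` defaults to all axes; pass ``(1, 2)`` for a batch of 2D
    slices shaped ``(B, H, W)``.
    """
    params = params or MINDParams()
    x = np.asarray(getattr(vol, "voxels", vol))
    if x.dtype not in (np.float32, np.float64):
        x = x.astype(np.float32)
    spatial_axes = tuple(range(x.ndim)) if spatial_axes is None else tuple(spatial_axes)
    offsets = params.resolved_offsets(len(spatial_axes))
    taps = params.taps()
    smooth_axes = spatial_axes[-2:]  # in-plane only; through-plane radius 0
    dps = []
    for o in offsets:
        d = (x - _shift_np(x, o, spatial_axes)) ** 2
        dps.append(_smooth_np(d, taps, smooth_axes))
    dp = np.stack(dps, axis=0)
    v = dp.mean(axis=0)
    floor = params.eps_frac * max(float(v.mean()), 1e-30)
    v = np.maximum(v, floor)
    desc = np.exp(-dp / v[None])
    desc /= desc.max(axis=0, keepdims=True)
    return desc


def mind_loss(i1, i2, params: MINDParams | None = None, region: np.ndarray | None = None) -> float:
    """Mean absolute channel difference between the two descriptor fields."""
    params = params or MINDParams()
    a = np.asarray(getattr(i1, "voxels", i1), dtype=np.float32)
    b = np.asarray(getattr(i2, "voxels", i2), dtype=np.float32)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d1 = mind_descriptor(a, params)
    d2 = mind_descriptor(b, params)
    diff = np.abs(d1 - d2).mean(axis=0)
    if region is not None:
        if not region.any():
            raise ValueError("empty region")
        return float(diff[region.astype(bool)].mean())
    return float(diff.mean())


# --------------------------------------------------------------- autodiff path
def _shift_t(x: Tensor, offset, spatial_axes) -> Tensor:
    for ax, o in zip(spatial_axes, offset):
        if o != 0:
            x = x.shift(ax, o)
    return x


def _smooth_t(x: Tensor, taps: np.ndarray, axes) -> Tensor:
    if len(taps) == 1:
        return x
    r = len(taps) // 2
    for ax in axes:
        acc = x * float(taps[r])
        for k in range(1, r + 1):
            acc = acc + x.shift(ax, k) * float(taps[r + k])
            acc = acc + x.shift(ax, -k) * float(taps[r - k])
        x = acc
    return x


def _tmax(a: Tensor, b: Tensor) -> Tensor:
    return (a + b + (a - b).abs()) * 0.5


def mind_descriptor_t(x: Tensor, params: MINDParams, spatial_axes: tuple) -> Tensor:
    """Autodiff descriptor; channels stacked on a new leading axis."""
    offsets = params.resolved_offsets(len(spatial_axes))
    taps = params.taps()
    smooth_axes = spatial_axes[-2:]
    dps = []
    for o in offsets:
        d = (x - _shift_t(x, o, spatial_axes)).square()
        dps.append(_smooth_t(d, taps, smooth_axes))
    dp = stack(dps, axis=0)
    v = dp.mean(axis=0, keepdims=True)
    floor = v.mean() * params.eps_frac
    v = _tmax(v, floor + Tensor(np.float32(1e-30)))
    desc = (-(dp / v)).exp()
    return desc / desc.max(axis=0, keepdims=True)


def mind_loss_t(
    x: Tensor,
    fixed_desc: np.ndarray,
    params: MINDParams,
    spatial_axes: tuple,
    region: np.ndarray | None = None,
) -> Tensor:
    """Differentiable MIND loss of ``x`` against a precomputed descriptor."""
    desc = mind_descriptor_t(x, params, spatial_axes)
    diff = (desc - Tensor(fixed_desc)).abs().mean(axis=0)
    if region is not None:
        wsum = float(region.sum())
        if wsum == 0:
            raise ValueError("empty region")
        return (diff * Tensor(region.astype(np.float32))).sum() * (1.0 / wsum)
    return diff.mean()
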