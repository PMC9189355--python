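"""Preprocessing chain: skin mask, couch removal, air fill, resampling,
rigid alignment, centered cropping, and the two intensity normalizations.

The chain order is: skin mask (couch excluded) → fill outside body with air
(−1000 HU) → resample to target spacing → rigid alignment of the CT onto the
CBCT → in-plane crop centered on the skin centroid. Registration inputs are
then clipped to [−250, 200] HU and mapped linearly to (−1, 1); synthesis
inputs use tanh(HU/400).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core_io import AIR_HU, ImageVolume
from .metrics import ncc


@dataclasses.dataclass
class RigidTransform:
    """Translation (tz, ty, tx) in mm plus in-plane rotation about z (deg)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.translation)) or not np.isfinite(self.rotation_deg):
            raise ValueError("transform components must be finite")
        if not -180.0 < self.rotation_deg <= 180.0:
            raise ValueError("rotation must be in (-180, 180]")


@dataclasses.dataclass
class PreprocessConfig:
    skin_threshold_hu: float = -300.0
    morph_radius: int = 2
    target_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    crop_size: tuple[int, int] = (288, 400)  # (ny, nx)
    clip_range: tuple[float, float] = (-250.0, 200.0)
    tanh_divisor: float = 400.0
    max_rotation_deg: float = 4.0
    max_translation_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip range must have low < high")
        ny, nx = self.crop_size
        if ny <= 0 or nx <= 0 or ny % 2 or nx % 2:
            raise ValueError("crop dims must be positive and even")
        if self.tanh_divisor <= 0:
            raise ValueError("tanh divisor must be positive")


def desk_config() -> PreprocessConfig:
    """Desk-scale preset: 5×2×2 mm grid, 96×128 in-plane crop."""
    return PreprocessConfig(target_spacing=(5.0, 2.0, 2.0), crop_size=(96, 128))


def paper_config() -> PreprocessConfig:
    return PreprocessConfig()


def extract_skin_mask(vol: ImageVolume, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Body mask by thresholding + closing + largest component + hole fill.

    Components touching the posterior/inferior image border whose vertical
    (y) extent is below 20% of the overall above-threshold extent are treated
    as couch and removed before picking the largest component.
    """
    cfg = cfg or PreprocessConfig()
    raw = vol.voxels > cfg.skin_threshold_hu
    if not raw.any():
        raise ValueError("no voxels above the skin threshold")
    if cfg.morph_radius > 0:
        # close in-plane only: slices are thick, and per-slice morphology
        # avoids eroding the body at the first/last slice faces
        structure = np.zeros((3, 3, 3), bool)
        structure[1] = ndimage.generate_binary_structure(2, 1)
        closed = ndimage.binary_closing(
            raw, structure=structure, iterations=cfg.morph_radius, border_value=0
        )
    else:
        closed = raw
    lab, n = ndimage.label(closed)
    if n == 0:
        raise ValueError("empty mask after morphology")
    ys = np.where(raw.any(axis=(0, 2)))[0]
    full_extent = ys.max() - ys.min() + 1
    ny = vol.shape[1]
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    for i in range(1, n + 1):
        comp = lab == i
        ys_i = np.where(comp.any(axis=(0, 2)))[0]
        extent_i = ys_i.max() - ys_i.min() + 1
        touches_border = comp[:, ny - 1, :].any()
        if touches_border and extent_i < 0.2 * full_extent:
            continue  # couch slab
        keep[i] = True
    if not keep.any():
        raise ValueError("all components rejected as couch")
    kept_sizes = np.where(keep[1:], sizes, 0)
    best = int(np.argmax(kept_sizes)) + 1
    mask = lab == best
    for z in range(mask.shape[0]):
        mask[z] = ndimage.binary_fill_holes(mask[z])
    return mask


def fill_outside_body(vol: ImageVolume, skin: np.ndarray) -> ImageVolume:
    """Set voxels outside the skin mask to air (−1000 HU) exactly."""
    skin = np.asarray(skin).astype(bool)
    if skin.shape != vol.shape:
        raise ValueError(f"mask {skin.shape} does not match volume {vol.shape}")
    out = vol.voxels.copy()
    out[~skin] = AIR_HU
    return vol.like(out)


def resample(vol: ImageVolume, target_spacing, fill: float = AIR_HU) -> ImageVolume:
    """Trilinear resampling onto a grid with the requested spacing.

    The output covers the same physical extent (voxel centers anchored at the
    volume origin); out-of-extent samples read ``fill``.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if target_spacing == vol.spacing:
        return vol.copy()
    new_shape = tuple(
        max(int(round(n * s / t)), 1)
        for n, s, t in zip(vol.shape, vol.spacing, target_spacing)
    )
    coords = np.meshgrid(
        *[
            np.arange(n, dtype=np.float32) * t / s
            for n, s, t in zip(new_shape, vol.spacing, target_spacing)
        ],
        indexing="ij",
    )
    # edge clamp: the sub-voxel sliver beyond the last voxel center replicates
    # the border instead of inventing background inside the field of view
    out = ndimage.map_coordinates(vol.voxels, coords, order=1, mode="nearest")
    return ImageVolume(out, target_spacing, vol.origin)


def _apply_rigid(moving: ImageVolume, t: RigidTransform, center_vox) -> np.ndarray:
    """Sample ``moving`` at rigidly transformed fixed-grid coordinates."""
    theta = np.deg2rad(t.rotation_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    # rotation about z in the (y, x) plane around center_vox, then translation
    mat = np.array([[1, 0, 0], [0, cos, -sin], [0, sin, cos]], dtype=np.float64)
    tvox = np.array([t.translation[d] / moving.spacing[d] for d in range(3)])
    center = np.asarray(center_vox, dtype=np.float64)
    offset = center - mat @ center + tvox
    return ndimage.affine_transform(
        moving.voxels, mat, offset=offset, order=1, mode="constant", cval=AIR_HU
    )


def rigid_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    moving_skin: np.ndarray,
    fixed_skin: np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> tuple[RigidTransform, ImageVolume]:
    """Skin-centroid translation plus a local NCC search (translation ± z-rotation).

    Returns the transform and the moving image resampled into the fixed grid
    (the output z-extent equals the fixed z-extent). The search only accepts
    NCC improvements over the centroid initialization.
    """
    cfg = cfg or PreprocessConfig()
    if not moving_skin.any() or not fixed_skin.any():
        raise ValueError("empty skin mask")
    lo, hi = cfg.clip_range

    def clipped(a):
        return np.clip(a, lo, hi)

    c_mov = np.array(ndimage.center_of_mass(moving_skin))
    c_fix = np.array(ndimage.center_of_mass(fixed_skin))
    init_t = [(c_mov[d] - c_fix[d]) * moving.spacing[d] for d in range(3)]
    center_vox = c_fix

    fx = clipped(fixed.voxels)

    def score(t: RigidTransform) -> float:
        return ncc(fx, clipped(_apply_rigid(moving, t, center_vox)))

    best = RigidTransform(tuple(init_t), 0.0)
    best_score = score(best)

    sz, sy, sx = moving.spacing
    steps = [
        (2 * sz, 2 * sy, 2 * sx, 2.0),
        (sz, sy, sx, 1.0),
        (sz / 2, sy / 2, sx / 2, 0.5),
    ]
    for dz_mm, dy_mm, dx_mm, rot_step in steps:
        improved = True
        while improved:
            improved = False
            tz, ty, tx = best.translation
            rot = best.rotation_deg
            candidates = []
            for delta, idx in (((dz_mm, 0, 0), 0), ((0, dy_mm, 0), 1), ((0, 0, dx_mm), 2)):
                for sgn in (1, -1):
                    nt = [tz, ty, tx]
                    nt[idx] += sgn * delta[idx]
                    if abs(nt[idx] - init_t[idx]) <= cfg.max_translation_mm:
                        candidates.append(RigidTransform(tuple(nt), rot))
            if cfg.max_rotation_deg > 0:
                for sgn in (1, -1):
                    nr = rot + sgn * rot_step
                    if abs(nr) <= cfg.max_rotation_deg:
                        candidates.append(RigidTransform((tz, ty, tx), nr))
            for cand in candidates:
                s = score(cand)
                if s > best_score + 1e-9:
                    best, best_score = cand, s
                    improved = True
    aligned = ImageVolume(_apply_rigid(moving, best, center_vox), fixed.spacing, fixed.origin)
    return best, aligned


def crop_offsets(skin: np.ndarray, size: tuple[int, int]) -> tuple[int, int]:
    """Top-left (y0, x0) of the crop window centered on the skin centroid.

    The centroid lands on the central voxel with the floor convention for
    even sizes; offsets may be negative (the crop then pads).
    """
    if not np.asarray(skin).any():
        raise ValueError("empty skin mask")
    _, cy, cx = ndimage.center_of_mass(np.asarray(skin).astype(bool))
    ny, nx = size
    return int(np.floor(cy)) - ny // 2, int(np.floor(cx)) - nx // 2


def crop_centered(
    vol: ImageVolume,
    skin: np.ndarray,
    size: tuple[int, int],
    fill: float = AIR_HU,
    offsets: tuple[int, int] | None = None,
) -> ImageVolume:
    """Crop each slice to ``(ny, nx)`` around the skin centroid, padding with air."""
    ny, nx = int(size[0]), int(size[1])
    if ny <= 0 or nx <= 0:
        raise ValueError("crop size must be positive")
    y0, x0 = offsets if offsets is not None else crop_offsets(skin, (ny, nx))
    nz = vol.shape[0]
    out = np.full((nz, ny, nx), fill, dtype=vol.voxels.dtype)
    ys0, ys1 = max(y0, 0), min(y0 + ny, vol.shape[1])
    xs0, xs1 = max(x0, 0), min(x0 + nx, vol.shape[2])
    if ys1 > ys0 and xs1 > xs0:
        out[:, ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = vol.voxels[:, ys0:ys1, xs0:xs1]
    return ImageVolume(out, vol.spacing, vol.origin)


def normalize_registration(vol, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Clip to [−250, 200] HU, then map linearly onto (−1, 1) endpoints-inclusive."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.clip_range
    x = np.clip(np.asarray(getattr(vol, "voxels", vol), dtype=np.float32), lo, hi)
    return (2.0 * (x - lo) / (hi - lo) - 1.0).astype(np.float32)


def normalize_tanh(vol, divisor: float = 400.0) -> np.ndarray:
    """tanh(HU / divisor) — the synthesis-branch normalization."""
    x = np.asarray(getattr(vol, "voxels", vol), dtype=np.float32)
    return np.tanh(x / divisor)


def inverse_tanh(
    norm: np.ndarray, divisor: float = 400.0, hu_limit: float = 1200.0
) -> np.ndarray:
    """Inverse of :func:`normalize_tanh`.

    Values are clamped so the output stays within ``±hu_limit`` HU: atanh
    diverges at ±1, and generator outputs arbitrarily close to saturation
    would otherwise map to physically meaningless intensities.
    """
    cap = np.tanh(hu_limit / divisor)
    y = np.clip(np.asarray(norm, dtype=np.float32), -cap, cap)
    return (divisor * np.arctanh(y)).astype(np.float32)
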