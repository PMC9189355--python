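"""Digital pelvic phantom: paired CT/CBCT volumes with ground truth.

The phantom emulates a female pelvis with geometric primitives — an
elliptic-cylinder body, an ellipsoidal bladder, a spinal-cord cylinder inside
a bony vertebral ring, spherical femoral heads and paired iliac bone-marrow
segments — rasterized in HU. A CBCT of the pair is the CT warped by a known
smooth deformation (with a controllable bladder-volume mismatch folded in)
plus additive CBCT-style degradation: noise, low-frequency shading, streaks
and an optional cavity artifact. Ground-truth labels and the deformation are
retained, standing in for manual contours on clinical scans.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core_io import AIR_HU, DEFAULT_ORGAN_TABLE, ImageVolume, LabelMap
from .fields import compose, warp
from .metrics import mask_volume_mm3, volume_diff


@dataclasses.dataclass
class PhantomSpec:
    """Anatomy description; lengths in mm, HU means within [-1000, 1500].

    ``bladder_scale`` multiplies the bladder's linear size (volume scales with
    its cube). ``grid_shape`` is (nz, ny, nx); ``spacing`` is (sz, sy, sx).
    """

    grid_shape: tuple[int, int, int] = (48, 96, 128)
    spacing: tuple[float, float, float] = (5.0, 2.0, 2.0)
    body_half_axes: tuple[float, float, float] = (1e6, 80.0, 110.0)
    bladder_center: tuple[float, float, float] = (0.0, -25.0, 0.0)
    bladder_half_axes: tuple[float, float, float] = (25.0, 27.0, 30.0)
    cord_center_yx: tuple[float, float] = (48.0, 0.0)
    cord_radius: float = 6.0
    vertebra_radius: float = 16.0
    femoral_center: tuple[float, float, float] = (0.0, 5.0, 72.0)  # |x| mirrored
    femoral_radius: float = 21.0
    marrow_center: tuple[float, float, float] = (0.0, 25.0, 45.0)  # |x| mirrored
    marrow_half_axes: tuple[float, float, float] = (35.0, 22.0, 16.0)
    # urine ~0-10 HU vs pelvic muscle/soft tissue ~45-55 HU: the bladder is a
    # low-attenuation structure a delineator can follow even on CBCT
    hu_means: dict = dataclasses.field(
        default_factory=lambda: {
            "soft": 45.0,
            "bladder": 2.0,
            "spinal_cord": 85.0,
            "bone": 700.0,
            "bone_marrow": 300.0,
        }
    )
    jitter_sd: float = 5.0
    bladder_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bladder_scale <= 0:
            raise ValueError("bladder_scale must be positive")
        for v in self.hu_means.values():
            if not -1000.0 <= v <= 1500.0:
                raise ValueError(f"HU mean {v} outside [-1000, 1500]")


@dataclasses.dataclass
class DegradationSpec:
    """Additive CBCT degradation model (amplitudes in HU).

    Defaults emulate an iteratively reconstructed CBCT: statistical
    reconstruction keeps the noise moderate, while residual scatter shading
    (bias field), streaks and cavity artifacts remain the dominant defects.
    """

    noise_sd: float = 18.0
    bias_amplitude: float = 60.0
    bias_correlation_mm: float = 80.0
    streak_count: int = 6
    streak_amplitude: float = 40.0
    cavity: bool = False
    cavity_depth: float = 80.0
    global_offset: float = 0.0
    couch: bool = False
    couch_hu: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "bias_amplitude", "streak_amplitude", "cavity_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bias_correlation_mm <= 0:
            raise ValueError("bias_correlation_mm must be positive")


@dataclasses.dataclass
class DeformationSpec:
    """Smooth random deformation from perturbed control points.

    ``max_displacement_mm`` bounds the dense field's vector norm (mm); keeping
    it below a third of the control spacing keeps the map invertible. The
    field is weighted toward the volume center (``center_weight_floor`` +
    Gaussian bump of width ``center_weight_sigma`` in normalized coordinates):
    inter-fraction pelvic deformation is dominated by internal soft-tissue
    motion while the skin outline and lateral bony periphery stay put.
    ``z_scale`` damps the through-plane component: with 5 mm slices,
    inter-fraction through-plane displacement is small relative to in-plane
    soft-tissue shifts and is barely representable at slice resolution.
    """

    control_spacing_mm: tuple[float, float, float] = (25.0, 40.0, 40.0)
    max_displacement_mm: float = 12.0
    smooth_sigma_ctrl: float = 1.0
    center_weight_floor: float = 0.2
    center_weight_sigma: float = 0.35
    z_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_displacement_mm < 0:
            raise ValueError("max_displacement_mm must be >= 0")
        if self.smooth_sigma_ctrl < 0:
            raise ValueError("smooth_sigma_ctrl must be >= 0")
        if not 0 <= self.center_weight_floor <= 1:
            raise ValueError("center_weight_floor must be in [0, 1]")


@dataclasses.dataclass
class PhantomPair:
    """A planning-CT / CBCT pair with full ground truth."""

    pct: ImageVolume
    pct_labels: LabelMap
    cbct: ImageVolume
    cbct_labels: LabelMap
    cbct_clean: ImageVolume  # warped CT before degradation: the sCT target
    true_field: np.ndarray  # (nz,ny,nx,3) voxel units, maps CBCT grid -> pCT
    achieved_bladder_diff: float


def _coords_mm(spec: PhantomSpec):
    """Meshgrid of physical coordinates (mm) relative to the volume center."""
    axes = [
        (np.arange(n, dtype=np.float32) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(z, y, x, center, half_axes) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax_ = half_axes
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMap]:
    """Rasterize the phantom anatomy; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    z, y, x = _coords_mm(spec)
    hu = spec.hu_means
    table = dict(DEFAULT_ORGAN_TABLE)

    body = _ellipsoid(z, y, x, (0, 0, 0), spec.body_half_axes)
    vol = np.full(spec.grid_shape, AIR_HU, dtype=np.float32)
    vol[body] = hu["soft"]
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[body] = table["body"]

    organ_masks: dict[str, np.ndarray] = {}

    s = spec.bladder_scale
    organ_masks["bladder"] = _ellipsoid(
        z, y, x, spec.bladder_center, tuple(a * s for a in spec.bladder_half_axes)
    )

    cy, cx = spec.cord_center_yx
    r2 = (y - cy) ** 2 + (x - cx) ** 2
    vertebra = r2 <= spec.vertebra_radius**2
    cord = r2 <= spec.cord_radius**2
    vol[vertebra & body] = hu["bone"]
    organ_masks["spinal_cord"] = cord

    fz, fy, fx = spec.femoral_center
    for name, sign in (("femoral_head_l", -1.0), ("femoral_head_r", 1.0)):
        organ_masks[name] = _ellipsoid(z, y, x, (fz, fy, sign * fx), (spec.femoral_radius,) * 3)

    mz, my, mx = spec.marrow_center
    marrow = _ellipsoid(z, y, x, (mz, my, -mx), spec.marrow_half_axes) | _ellipsoid(
        z, y, x, (mz, my, mx), spec.marrow_half_axes
    )
    organ_masks["bone_marrow"] = marrow

    organ_hu = {
        "bladder": hu["bladder"],
        "spinal_cord": hu["spinal_cord"],
        "femoral_head_l": hu["bone"],
        "femoral_head_r": hu["bone"],
        "bone_marrow": hu["bone_marrow"],
    }
    for name in ("bone_marrow", "femoral_head_l", "femoral_head_r", "bladder", "spinal_cord"):
        m = organ_masks[name]
        if not m.any():
            raise ValueError(f"organ {name} rasterized empty")
        if np.any(m & ~body):
            raise ValueError(f"organ {name} extends outside the body ellipsoid")
        vol[m] = organ_hu[name]
        labels[m] = table[name]

    if spec.jitter_sd > 0:
        vol[body] += rng.normal(0.0, spec.jitter_sd, size=int(body.sum())).astype(np.float32)

    geom = {"spacing": spec.spacing, "origin": (0.0, 0.0, 0.0)}
    return (
        ImageVolume(vol, **geom),
        LabelMap(labels, organ_table=table, **geom),
    )


def degrade_to_cbct(ct: ImageVolume, body: np.ndarray, spec: DegradationSpec) -> ImageVolume:
    """Add CBCT-style intensity corruption; anatomy (labels) is unchanged."""
    body = np.asarray(body).astype(bool)
    if body.shape != ct.shape:
        raise ValueError(f"body mask {body.shape} does not match volume {ct.shape}")
    rng = np.random.default_rng(spec.seed)
    out = ct.voxels.copy()
    nz, ny, nx = ct.shape

    if spec.bias_amplitude > 0:
        sig = [max(spec.bias_correlation_mm / s / 4.0, 0.5) for s in ct.spacing]
        raw = rng.standard_normal((nz, ny, nx)).astype(np.float32)
        bias = ndimage.gaussian_filter(raw, sigma=sig)
        peak = float(np.abs(bias[body]).max()) if body.any() else float(np.abs(bias).max())
        if peak > 0:
            bias *= spec.bias_amplitude / peak
        out[body] += bias[body]

    if spec.noise_sd > 0:
        out[body] += rng.normal(0.0, spec.noise_sd, size=int(body.sum())).astype(np.float32)

    if spec.streak_count > 0 and spec.streak_amplitude > 0:
        yy, xx = np.meshgrid(
            np.arange(ny, dtype=np.float32) - ny / 2,
            np.arange(nx, dtype=np.float32) - nx / 2,
            indexing="ij",
        )
        streaks = np.zeros((ny, nx), dtype=np.float32)
        for k in range(spec.streak_count):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(-0.3, 0.3) * min(ny, nx)
            dist = np.abs(np.cos(theta) * yy + np.sin(theta) * xx - offset)
            sign = 1.0 if k % 2 == 0 else -1.0
            streaks += sign * spec.streak_amplitude * np.exp(-(dist**2) / 2.0)
        out[body] += np.broadcast_to(streaks, (nz, ny, nx))[body]

    if spec.cavity and spec.cavity_depth > 0:
        # gas-pocket style dark blob in the posterior soft tissue
        zc = rng.uniform(0.35, 0.65) * nz
        yc = rng.uniform(0.55, 0.7) * ny
        xc = rng.uniform(0.4, 0.6) * nx
        zz = (np.arange(nz, dtype=np.float32) - zc)[:, None, None] * ct.spacing[0]
        yb = (np.arange(ny, dtype=np.float32) - yc)[None, :, None] * ct.spacing[1]
        xb = (np.arange(nx, dtype=np.float32) - xc)[None, None, :] * ct.spacing[2]
        rho2 = (zz / 15.0) ** 2 + (yb / 12.0) ** 2 + (xb / 12.0) ** 2
        out[body] -= (spec.cavity_depth * np.exp(-rho2)).astype(np.float32)[body]

    if spec.global_offset:
        out[body] += spec.global_offset

    if spec.couch:
        # slab at the posterior image border (below the patient)
        ys = np.where(body.any(axis=(0, 2)))[0]
        y0 = max(ny - 3, (int(ys.max()) + 6) if ys.size else 0)
        x0, x1 = int(0.1 * nx), int(0.9 * nx)
        out[:, y0:ny, x0:x1] = spec.couch_hu

    return ct.like(out)


def sample_deformation(
    spec: DeformationSpec, grid_shape, spacing, weight_center_mm=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Dense smooth random field (voxel units), zero in a boundary band.

    ``weight_center_mm`` places the center-emphasis bump (relative to the
    volume center); pair generation centers it on the bladder, where
    inter-fraction pelvic deformation concentrates.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    for c, s in zip(spec.control_spacing_mm, spacing):
        if c < 2 * s:
            raise ValueError(f"control spacing {c} mm < 2 voxels ({2 * s} mm)")
    rng = np.random.default_rng(spec.seed)
    field = np.zeros(grid_shape + (3,), dtype=np.float32)
    if spec.max_displacement_mm == 0:
        return field
    n_ctrl = [
        max(int(np.ceil(n * s / c)) + 3, 4)
        for n, s, c in zip(grid_shape, spacing, spec.control_spacing_mm)
    ]
    ctrl = rng.standard_normal((3, *n_ctrl)).astype(np.float32)
    if spec.smooth_sigma_ctrl > 0:
        for d in range(3):
            ctrl[d] = ndimage.gaussian_filter(ctrl[d], spec.smooth_sigma_ctrl)
    dense_mm = np.empty((3, *grid_shape), dtype=np.float32)
    for d in range(3):
        factors = [g / c for g, c in zip(grid_shape, n_ctrl)]
        comp = ndimage.zoom(ctrl[d], factors, order=3, mode="nearest", grid_mode=True)
        dense_mm[d] = comp[: grid_shape[0], : grid_shape[1], : grid_shape[2]]

    # taper to zero in a boundary band so the body outline is preserved
    for ax, n in enumerate(grid_shape):
        band = max(2, int(round(0.1 * n)))
        ramp = np.ones(n, dtype=np.float32)
        t = 0.5 * (1 - np.cos(np.pi * np.arange(band) / band))
        ramp[:band] = t
        ramp[n - band :] = t[::-1]
        shape = [1, 1, 1, 1]
        shape[ax + 1] = n
        dense_mm *= ramp.reshape(shape)

    # emphasize the region around ``weight_center_mm``: internal organs
    # deform while the periphery is stable
    axes_n = [
        np.linspace(-1.0, 1.0, n, dtype=np.float32) - 2.0 * c / (n * s)
        for n, s, c in zip(grid_shape, spacing, weight_center_mm)
    ]
    zz, yy, xx = np.meshgrid(*axes_n, indexing="ij")
    rho2 = zz**2 + yy**2 + xx**2
    w = spec.center_weight_floor + (1.0 - spec.center_weight_floor) * np.exp(
        -rho2 / (2.0 * spec.center_weight_sigma**2)
    )
    dense_mm *= w[None]
    dense_mm[0] *= spec.z_scale

    norm_mm = np.sqrt((dense_mm**2).sum(axis=0))
    peak = float(norm_mm.max())
    if peak > 0:
        dense_mm *= spec.max_displacement_mm / peak
    for d in range(3):
        field[..., d] = dense_mm[d] / spacing[d]
    return field


def _bladder_expansion_field(spec: PhantomSpec, scale: float, outer: float = 1.8) -> np.ndarray:
    """Field (voxel units) realizing a bladder linear re-scale by ``scale``.

    Inside the scaled bladder the map is the exact inverse scaling about the
    bladder center; outside it decays smoothly to zero by ``outer`` times the
    bladder radius, displacing surrounding soft tissue.
    """
    field = np.zeros(spec.grid_shape + (3,), dtype=np.float32)
    if scale == 1.0:
        return field
    z, y, x = _coords_mm(spec)
    c = spec.bladder_center
    half = tuple(a * scale for a in spec.bladder_half_axes)
    rho = np.sqrt(
        ((z - c[0]) / half[0]) ** 2 + ((y - c[1]) / half[1]) ** 2 + ((x - c[2]) / half[2]) ** 2
    )
    factor = np.zeros_like(rho, dtype=np.float32)
    inside = rho <= 1.0
    ring = (rho > 1.0) & (rho < outer)
    factor[inside] = 1.0 / scale - 1.0
    taper = 0.5 * (1.0 + np.cos(np.pi * (rho[ring] - 1.0) / (outer - 1.0)))
    factor[ring] = (1.0 / scale - 1.0) * taper.astype(np.float32)
    for d, rel in enumerate((z - c[0], y - c[1], x - c[2])):
        field[..., d] = factor * rel / spec.spacing[d]
    return field


def make_pair(
    spec: PhantomSpec,
    dspec: DegradationSpec,
    fspec: DeformationSpec,
    bladder_diff_target: float = 0.0,
) -> PhantomPair:
    """Generate a pCT/CBCT pair with a target bladder volume-difference.

    The CBCT anatomy is the pCT warped by the composition of a bladder
    re-scaling field and a random smooth field; the achieved bladder Diff is
    measured on the label maps and the scale corrected until it lands within
    10% (relative) of the target.
    """
    if bladder_diff_target < 0:
        raise ValueError("bladder_diff_target must be >= 0")
    if bladder_diff_target > 400:
        raise ValueError("bladder_diff_target > 400% is not reachable in this anatomy")
    pct, pct_labels = generate_phantom(spec)
    u_rand = sample_deformation(
        fspec, spec.grid_shape, spec.spacing, weight_center_mm=spec.bladder_center
    )

    target_ratio = 1.0 + bladder_diff_target / 100.0
    scale = target_ratio ** (1.0 / 3.0)
    pct_bladder_vol = mask_volume_mm3(pct_labels.labels == 2, spec.spacing)

    total = None
    achieved = 0.0
    cbct_labels_arr = pct_labels.labels
    for _ in range(4):
        u_b = _bladder_expansion_field(spec, scale)
        total = compose(u_b, u_rand)
        cbct_labels_arr = warp(pct_labels.labels, total, mode="nearest", fill=0)
        cbct_vol = mask_volume_mm3(cbct_labels_arr == 2, spec.spacing)
        achieved = volume_diff(cbct_vol, pct_bladder_vol)
        if bladder_diff_target == 0:
            break
        if abs(achieved - bladder_diff_target) <= 0.10 * bladder_diff_target:
            break
        scale *= ((1.0 + bladder_diff_target / 100.0) / (1.0 + achieved / 100.0)) ** (1.0 / 3.0)

    cbct_clean_arr = warp(pct.voxels, total, mode="linear", fill=AIR_HU)
    geom = {"spacing": spec.spacing, "origin": (0.0, 0.0, 0.0)}
    cbct_clean = ImageVolume(cbct_clean_arr, **geom)
    cbct_labels = LabelMap(cbct_labels_arr, organ_table=dict(pct_labels.organ_table), **geom)
    body = cbct_labels.labels > 0
    cbct = degrade_to_cbct(cbct_clean, body, dspec)
    return PhantomPair(
        pct=pct,
        pct_labels=pct_labels,
        cbct=cbct,
        cbct_labels=cbct_labels,
        cbct_clean=cbct_clean,
        true_field=total,
        achieved_bladder_diff=float(achieved),
    )
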