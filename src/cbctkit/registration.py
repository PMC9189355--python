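"""MSnet: a 3-stage coarse-to-fine displacement-field estimator trained
unsupervised with a MIND dissimilarity loss plus a diffusion smoothness loss,
together with field warping/composition and contour propagation.

Each stage runs at a fixed fraction of full resolution (1/4, 1/2, 1), sees
the (already warped) moving image and the fixed image as a 2-channel input,
and predicts a residual displacement field at its scale through an
encoder (2 stride-2 convolutions) → 6 residual blocks → decoder
(2 nearest-upsample + convolution) network whose output layer is
zero-initialized so optimization starts from the identity map. Stage fields
are upsampled and composed into one full-resolution map. At desk scale the
network is fit per image pair (instance optimization); the objective is the
same as for population training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor
from scipy import ndimage

from .fields import (
    compose,
    resize_field,
    warp,
    warp_t,
)
from .mind import MINDParams, mind_descriptor, mind_loss_t
from .nn import Adam, Conv3d, Module, ResBlock3d, upsample2
from .core_io import LabelMap

__all__ = [
    "MSNetConfig",
    "RegistrationResult",
    "build_msnet",
    "train_registration",
    "register",
    "propagate_contours",
    "smoothness_loss",
    "warp",
    "compose",
]


@dataclasses.dataclass
class MSNetConfig:
    """Cascade hyperparameters.

    ``scales`` are in-plane downsampling denominators per stage, coarse to
    fine and ending at 1 (the slice axis is left at native resolution: 5 mm
    slices are already coarse). ``iters`` is the per-stage optimization
    budget; most of it goes to the coarse stage, whose grid can already
    express smooth anatomical deformation, while the finer stages take
    conservative steps (``lr_scales``) under stronger smoothness
    (``smooth_scales``) and act as refinements. ``loss_smooth_sigma`` is an
    in-plane Gaussian prefilter (voxels) applied to both images before the
    dissimilarity, a standard noise-robustness measure. The ``batches``
    values describe full-scale population training; desk instance fitting
    uses batch 1 throughout.
    """

    stages: int = 3
    scales: tuple[int, ...] = (4, 2, 1)
    iters: tuple[int, ...] = (180, 100, 8)
    batches: tuple[int, ...] = (20, 4, 1)
    base_channels: int = 8
    n_resblocks: int = 6
    w_mind: float = 1.0
    w_smooth: float = 3.0
    lr: float = 2e-3
    grad_clip: float = 1.0
    lr_scales: tuple[float, ...] = (1.0, 0.5, 0.15)
    smooth_scales: tuple[float, ...] = (1.0, 2.0, 4.0)
    loss_smooth_sigma: float = 1.0
    seed: int = 0
    mind: MINDParams = dataclasses.field(default_factory=MINDParams)

    def __post_init__(self) -> None:
        if self.stages < 1 or len(self.scales) != self.stages:
            raise ValueError("scales must have one entry per stage")
        if list(self.scales) != sorted(self.scales, reverse=True) or self.scales[-1] != 1:
            raise ValueError("scales must descend and end at 1")
        if len(self.iters) != self.stages or len(self.lr_scales) != self.stages:
            raise ValueError("iters and lr_scales must have one entry per stage")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")


@dataclasses.dataclass
class RegistrationResult:
    field: np.ndarray  # composed full-resolution field (nz,ny,nx,3)
    stage_fields: list[np.ndarray]
    loss_history: list[dict]


class StageNet(Module):
    """One cascade stage: 2-channel pair in, 3-channel residual field out."""

    def __init__(self, rng: np.random.Generator, base: int, n_res: int):
        c = base
        self.conv_in = Conv3d(rng, 2, c)
        self.down1 = Conv3d(rng, c, 2 * c, stride=2)
        self.down2 = Conv3d(rng, 2 * c, 4 * c, stride=2)
        self.res = [ResBlock3d(rng, 4 * c) for _ in range(n_res)]
        self.up1 = Conv3d(rng, 4 * c, 2 * c)
        self.up2 = Conv3d(rng, 2 * c, c)
        self.out = Conv3d(rng, c, 3, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.data.shape[1:]
        if any(n % 4 for n in shape):
            raise ValueError(
                f"stage input {shape} not divisible by 4 (two down-samplings); pad the volume"
            )
        h = self.conv_in(x).leaky_relu(0.2)
        h = self.down1(h).leaky_relu(0.2)
        h = self.down2(h).leaky_relu(0.2)
        for block in self.res:
            h = block(h)
        h = self.up1(upsample2(h, (1, 2, 3))).leaky_relu(0.2)
        h = self.up2(upsample2(h, (1, 2, 3))).leaky_relu(0.2)
        return self.out(h)


class RegistrationModel:
    """Trained (or fresh) cascade: one :class:`StageNet` per stage."""

    def __init__(self, cfg: MSNetConfig):
        self.cfg = cfg
        root = np.random.SeedSequence(cfg.seed)
        self.nets = [
            StageNet(np.random.default_rng(s), cfg.base_channels, cfg.n_resblocks)
            for s in root.spawn(cfg.stages)
        ]

    def params(self) -> list[Tensor]:
        out = []
        for net in self.nets:
            out.extend(net.params())
        return out


def build_msnet(cfg: MSNetConfig | None = None) -> RegistrationModel:
    return RegistrationModel(cfg or MSNetConfig())


def smoothness_loss(field: np.ndarray) -> float:
    """Mean squared forward-difference gradient of the field.

    For every component and spatial axis the forward difference is taken with
    the trailing edge contributing zero; the loss is the mean of all nine
    squared gradient maps over all voxels.
    """
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[3] != 3:
        raise ValueError(f"field must be (nz,ny,nx,3), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    total = 0.0
    for d in range(3):
        comp = field[..., d]
        for ax in range(3):
            diff = np.zeros_like(comp)
            sl_hi = [slice(None)] * 3
            sl_lo = [slice(None)] * 3
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            diff[tuple(sl_lo)] = comp[tuple(sl_hi)] - comp[tuple(sl_lo)]
            total += float((diff**2).mean())
    return total / 9.0


def _smoothness_t(field: Tensor) -> Tensor:
    """Autodiff version of :func:`smoothness_loss` for (3, D, H, W) tensors."""
    total = None
    for ax in (1, 2, 3):
        diff = field.shift(ax, 1) - field  # clamped shift → zero at trailing edge
        term = diff.square().mean()
        total = term if total is None else total + term
    return total * (1.0 / 3.0)


def _check_normalized(vol: np.ndarray, name: str) -> np.ndarray:
    vol = np.asarray(vol, dtype=np.float32)
    if vol.min() < -1.001 or vol.max() > 1.001:
        raise ValueError(f"{name} must be normalized to (-1, 1) before registration")
    return vol


def _pool_inplane(vol: np.ndarray, factor: int) -> np.ndarray:
    z, y, x = vol.shape
    if y % factor or x % factor:
        raise ValueError(f"in-plane shape {(y, x)} not divisible by {factor}")
    return (
        vol.reshape(z, y // factor, factor, x // factor, factor)
        .mean(axis=(2, 4))
        .astype(np.float32)
    )


def _stage_inputs(moving_w, fixed, region, scale, sigma=0.0):
    if scale == 1:
        m, f, r = moving_w, fixed, region
    else:
        m = _pool_inplane(moving_w, scale)
        f = _pool_inplane(fixed, scale)
        r = (
            _pool_inplane(region.astype(np.float32), scale) > 0.25
            if region is not None
            else None
        )
    if sigma > 0:
        m = ndimage.gaussian_filter(m, (0, sigma, sigma))
        f = ndimage.gaussian_filter(f, (0, sigma, sigma))
    return m, f, r


def _fit_stage(net, stage_data, cfg, stage_idx, history):
    """Optimize one stage on one or more pairs; returns per-pair residual fields.

    ``stage_data`` is a list of (m_s, f_s, fixed_desc, region) tuples at the
    stage scale; iterations cycle through the pairs (batch 1).
    """
    opt = Adam(net.params(), lr=cfg.lr * cfg.lr_scales[stage_idx], grad_clip=cfg.grad_clip)
    w_smooth = cfg.w_smooth * cfg.smooth_scales[stage_idx]
    inputs = [Tensor(np.stack([m, f], axis=0)) for m, f, _, _ in stage_data]
    for it in range(cfg.iters[stage_idx]):
        m_s, f_s, fixed_desc, region_np = stage_data[it % len(stage_data)]
        inp = inputs[it % len(stage_data)]
        opt.zero_grad()
        r = net(inp)
        warped = warp_t(m_s, r)
        l_mind = mind_loss_t(warped, fixed_desc, cfg.mind, (0, 1, 2), region_np)
        l_smooth = _smoothness_t(r)
        loss = l_mind * cfg.w_mind + l_smooth * w_smooth
        loss.backward()
        opt.step()
        history.append(
            {
                "stage": stage_idx,
                "mind": float(l_mind.data),
                "smooth": float(l_smooth.data),
                "total": float(loss.data),
            }
        )
    return [np.moveaxis(net(inp).data, 0, -1) for inp in inputs]  # (D,H,W,3) each


def train_registration(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: MSNetConfig | None = None,
    region: np.ndarray | None = None,
) -> tuple[RegistrationModel, RegistrationResult]:
    """Fit the cascade on normalized (moving, fixed) pairs, coarse to fine.

    Stage k warps the moving image by the composed field of earlier stages,
    downsamples to the stage scale and minimizes
    ``w_mind·L_MIND(warp(moving, residual), fixed) + w_smooth·L_smooth(residual)``.
    With a single pair this is instance fitting (the desk preset); with
    several pairs the stages cycle through them.
    """
    cfg = cfg or MSNetConfig()
    if not pairs:
        raise ValueError("need at least one (moving, fixed) pair")
    model = build_msnet(cfg)
    norm_pairs = [
        (_check_normalized(m, "moving"), _check_normalized(f, "fixed")) for m, f in pairs
    ]

    history: list[dict] = []
    stage_fields: list[np.ndarray] = []  # residuals of the first pair, per stage
    prevs = [np.zeros(f.shape + (3,), dtype=np.float32) for _, f in norm_pairs]
    for k, scale in enumerate(cfg.scales):
        stage_data = []
        for (moving, fixed), prev in zip(norm_pairs, prevs):
            moving_w = warp(moving, prev, mode="linear", fill=-1.0)
            m_s, f_s, r_s = _stage_inputs(moving_w, fixed, region, scale, cfg.loss_smooth_sigma)
            stage_data.append(
                (
                    m_s,
                    f_s,
                    mind_descriptor(f_s, cfg.mind),
                    r_s.astype(np.float32) if r_s is not None else None,
                )
            )
        residuals = _fit_stage(model.nets[k], stage_data, cfg, k, history)
        stage_fields.append(residuals[0])
        for i, r_stage in enumerate(residuals):
            shape_i = norm_pairs[i][1].shape
            r_full = resize_field(r_stage, shape_i) if scale != 1 else r_stage
            prevs[i] = compose(prevs[i], r_full)
    result = RegistrationResult(field=prevs[0], stage_fields=stage_fields, loss_history=history)
    return model, result


def register(
    model: RegistrationModel, moving: np.ndarray, fixed: np.ndarray, region: np.ndarray | None = None
) -> RegistrationResult:
    """Run the trained cascade: per-stage prediction, upsampling, composition."""
    cfg = model.cfg
    moving = _check_normalized(moving, "moving")
    fixed = _check_normalized(fixed, "fixed")
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    full_shape = fixed.shape
    prev = np.zeros(full_shape + (3,), dtype=np.float32)
    stage_fields = []
    for k, scale in enumerate(cfg.scales):
        moving_w = warp(moving, prev, mode="linear", fill=-1.0)
        m_s, f_s, _ = _stage_inputs(moving_w, fixed, region, scale, cfg.loss_smooth_sigma)
        r = model.nets[k](Tensor(np.stack([m_s, f_s], axis=0)))
        r_stage = np.moveaxis(r.data, 0, -1)
        stage_fields.append(r_stage)
        r_full = resize_field(r_stage, full_shape) if scale != 1 else r_stage
        prev = compose(prev, r_full)
    return RegistrationResult(field=prev, stage_fields=stage_fields, loss_history=[])


def propagate_contours(labels: LabelMap, field: np.ndarray) -> LabelMap:
    """Nearest-neighbor warp of a label map by a displacement field."""
    field = np.asarray(field, dtype=np.float32)
    if field.shape[:3] != labels.shape:
        raise ValueError(f"label grid {labels.shape} does not match field {field.shape[:3]}")
    warped = warp(labels.labels, field, mode="nearest", fill=0)
    return LabelMap(warped, labels.spacing, labels.origin, dict(labels.organ_table))
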