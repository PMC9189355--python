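"""CycleGAN for CBCT → synthetic-CT translation.

Two generators (CBCT→CT and CT→CBCT; U-net with 5 down-sampling levels or
ResNet with 15 residual blocks) and two patch discriminators are trained on
2D axial slices normalized by tanh(HU/400). The generator objective is

    ``L_G = L_adv + λ·L_cycle + μ·L_sc``        (λ = μ = 10)

with a least-squares adversarial term, L1 cycle-consistency reconstructions
in both directions, and a similarity constraint L_sc: the MIND loss between
each synthetic slice and its source slice, which ties the synthetic anatomy
to the input rather than to the training distribution. The step size is
constant for the first half of training and decays linearly to zero over the
second half.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, concat
from .core_io import ImageVolume
from .mind import MINDParams, mind_loss_t, mind_descriptor
from .nn import Adam, Conv2d, InstanceNorm2d, Module, ResBlock2d, upsample2
from .preprocess import inverse_tanh, normalize_tanh

__all__ = [
    "GeneratorConfig",
    "CycleGANConfig",
    "TrainHistory",
    "build_generator",
    "build_discriminator",
    "cyclegan_step",
    "train_cyclegan",
    "synthesize_ct",
    "scheduled_lr",
]


@dataclasses.dataclass
class GeneratorConfig:
    """Generator architecture.

    ``input_residual`` adds a global skip: the head predicts a correction in
    pre-tanh (scaled-HU) space that is added to the input before the final
    tanh, so a freshly initialized generator is the identity map. For
    CBCT→CT translation the output is a corrected version of the input, and
    learning the correction converges far faster than re-learning the image.
    """

    kind: str = "resnet15"  # or "unet5"
    base_channels: int = 6  # desk-scale width; widen for larger slices
    n_resblocks: int = 15
    unet_levels: int = 5
    input_residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("resnet15", "unet5"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")


@dataclasses.dataclass
class CycleGANConfig:
    """Training hyperparameters.

    Defaults describe full-scale training: 200 epochs with the generator
    step size 0.002 held for the first half and decayed linearly to zero
    over the second half, batch 6, cycle and similarity weights of 10.
    ``disc_rate`` is the discriminator step-size knob; the desk presets use
    0.02 (a discriminator that learns faster than the generators), the
    default is a conventional conservative value.
    """

    lambda_cycle: float = 10.0
    mu_sc: float = 10.0
    batch: int = 6
    lr: float = 0.002
    disc_rate: float = 0.0002
    epochs: int = 200
    decay_epochs: int = 100
    steps_per_epoch: int | None = None  # cap on batches per epoch (subsampled SGD)
    disc_steps: int = 1  # discriminator updates per generator update
    pool_size: int = 50
    paired_batches: bool = False
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    mind: MINDParams = dataclasses.field(default_factory=MINDParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_cycle < 0 or self.mu_sc < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epochs < self.decay_epochs:
            raise ValueError("epochs must cover the decay span")


@dataclasses.dataclass
class TrainHistory:
    adv: list[float]
    cycle: list[float]
    sc: list[float]
    total: list[float]
    disc: list[float]

    def __post_init__(self) -> None:
        n = len(self.adv)
        if any(len(v) != n for v in (self.cycle, self.sc, self.total, self.disc)):
            raise ValueError("history columns must have equal length")


def scheduled_lr(epoch: int, cfg: CycleGANConfig) -> float:
    """Step size at 1-based ``epoch``: constant, then linear decay to zero."""
    start = cfg.epochs - cfg.decay_epochs
    if epoch <= start:
        return cfg.lr
    return cfg.lr * (cfg.epochs - epoch) / cfg.decay_epochs


def _pad_to(x: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        x = np.pad(x, [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)], mode="edge")
    return x, (h, w)


_ATANH_CLIP = 0.995  # pre-image of roughly ±1200 HU under tanh(x/400)


def _residual_head(head_out: Tensor, x: Tensor) -> Tensor:
    return (head_out + x.clip(-_ATANH_CLIP, _ATANH_CLIP).atanh()).tanh()


class ResNetGenerator(Module):
    """c7s1 stem, 2 stride-2 down-samplings, N residual blocks, 2 up-samplings."""

    def __init__(self, rng, base: int, n_res: int, input_residual: bool = True):
        c = base
        self.stem = Conv2d(rng, 1, c, k=7)
        self.n_stem = InstanceNorm2d(c)
        self.d1 = Conv2d(rng, c, 2 * c, stride=2)
        self.nd1 = InstanceNorm2d(2 * c)
        self.d2 = Conv2d(rng, 2 * c, 4 * c, stride=2)
        self.nd2 = InstanceNorm2d(4 * c)
        self.res = [ResBlock2d(rng, 4 * c) for _ in range(n_res)]
        self.u1 = Conv2d(rng, 4 * c, 2 * c)
        self.nu1 = InstanceNorm2d(2 * c)
        self.u2 = Conv2d(rng, 2 * c, c)
        self.nu2 = InstanceNorm2d(c)
        self.head = Conv2d(rng, c, 1, k=7, zero_init=input_residual)
        self.input_residual = input_residual
        self.mult = 4

    def __call__(self, x: Tensor) -> Tensor:
        h = self.n_stem(self.stem(x)).relu()
        h = self.nd1(self.d1(h)).relu()
        h = self.nd2(self.d2(h)).relu()
        for block in self.res:
            h = block(h)
        h = self.nu1(self.u1(upsample2(h, (2, 3)))).relu()
        h = self.nu2(self.u2(upsample2(h, (2, 3)))).relu()
        out = self.head(h)
        if self.input_residual:
            return _residual_head(out, x)
        return out.tanh()


class UNetGenerator(Module):
    """Encoder–decoder with skip connections and ``levels`` down-samplings."""

    def __init__(self, rng, base: int, levels: int, input_residual: bool = True):
        self.levels = levels
        self.input_residual = input_residual
        chans = [min(base * 2**i, 8 * base) for i in range(levels)]
        self.stem = Conv2d(rng, 1, base)
        self.downs = []
        c_prev = base
        for c in chans:
            self.downs.append(Conv2d(rng, c_prev, c, stride=2))
            c_prev = c
        self.ups = []
        for i in reversed(range(levels)):
            c_skip = chans[i - 1] if i > 0 else base
            self.ups.append(Conv2d(rng, c_prev + c_skip, c_skip))
            c_prev = c_skip
        self.head = Conv2d(rng, base, 1, k=7, zero_init=input_residual)
        self.mult = 2**levels

    def params(self) -> list[Tensor]:
        out = self.stem.params() + self.head.params()
        for m in self.downs + self.ups:
            out.extend(m.params())
        return out

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem(x).leaky_relu(0.2)
        skips = [h]
        for d in self.downs:
            h = d(h).leaky_relu(0.2)
            skips.append(h)
        for i, u in enumerate(self.ups):
            h = upsample2(h, (2, 3))
            skip = skips[self.levels - 1 - i]
            h = u(concat([h, skip], axis=1)).leaky_relu(0.2)
        out = self.head(h)
        if self.input_residual:
            return _residual_head(out, x)
        return out.tanh()


class GeneratorModel:
    """Generator plus the padding bookkeeping for arbitrary slice sizes."""

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.kind == "resnet15":
            self.net = ResNetGenerator(rng, cfg.base_channels, cfg.n_resblocks, cfg.input_residual)
        else:
            self.net = UNetGenerator(rng, cfg.base_channels, cfg.unet_levels, cfg.input_residual)

    def params(self):
        return self.net.params()

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[-2:]
        if h % self.net.mult or w % self.net.mult:
            raise ValueError(
                f"slice {h}x{w} not divisible by {self.net.mult}; pad inputs "
                f"(apply() pads automatically)"
            )
        return self.net(x)

    def apply(self, slices: np.ndarray) -> np.ndarray:
        """Forward a (B, H, W) array of normalized slices, padding as needed."""
        x, (h, w) = _pad_to(slices.astype(np.float32), self.net.mult)
        out = self.net(Tensor(x[:, None]))
        return out.data[:, 0, :h, :w]


class Discriminator(Module):
    """PatchGAN: a grid of realness scores with a ~70-pixel receptive field."""

    def __init__(self, rng, base: int = 8):
        c = base
        self.c1 = Conv2d(rng, 1, c, k=4, stride=2)
        self.c2 = Conv2d(rng, c, 2 * c, k=4, stride=2)
        self.n2 = InstanceNorm2d(2 * c)
        self.c3 = Conv2d(rng, 2 * c, 4 * c, k=4, stride=2)
        self.n3 = InstanceNorm2d(4 * c)
        self.c4 = Conv2d(rng, 4 * c, 8 * c, k=4)
        self.n4 = InstanceNorm2d(8 * c)
        self.head = Conv2d(rng, 8 * c, 1, k=4)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c1(x).leaky_relu(0.2)
        h = self.n2(self.c2(h)).leaky_relu(0.2)
        h = self.n3(self.c3(h)).leaky_relu(0.2)
        h = self.n4(self.c4(h)).leaky_relu(0.2)
        return self.head(h)


def build_generator(cfg: GeneratorConfig | None = None) -> GeneratorModel:
    return GeneratorModel(cfg or GeneratorConfig())


def build_discriminator(base: int = 8, seed: int = 0) -> Discriminator:
    return Discriminator(np.random.default_rng(seed), base)


class ImagePool:
    """History buffer of generated slices for discriminator updates."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.items) < self.size:
                self.items.append(img)
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(len(self.items)))
                out.append(self.items[idx])
                self.items[idx] = img
            else:
                out.append(img)
        return np.stack(out)


def _mse_to(t: Tensor, target: float) -> Tensor:
    return (t - target).square().mean()


@dataclasses.dataclass
class CycleGANModels:
    g_cbct_ct: GeneratorModel
    g_ct_cbct: GeneratorModel
    d_ct: Discriminator
    d_cbct: Discriminator
    opt_g: Adam
    opt_d: Adam
    pool_ct: ImagePool
    pool_cbct: ImagePool


def _build_models(cfg: CycleGANConfig) -> CycleGANModels:
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(5)
    gc = dataclasses.replace(cfg.generator, seed=seeds[0].generate_state(1)[0] % (2**31))
    gc2 = dataclasses.replace(cfg.generator, seed=seeds[1].generate_state(1)[0] % (2**31))
    g_ab = GeneratorModel(gc)
    g_ba = GeneratorModel(gc2)
    d_b = Discriminator(np.random.default_rng(seeds[2]), cfg.generator.base_channels)
    d_a = Discriminator(np.random.default_rng(seeds[3]), cfg.generator.base_channels)
    pool_rng = np.random.default_rng(seeds[4])
    return CycleGANModels(
        g_cbct_ct=g_ab,
        g_ct_cbct=g_ba,
        d_ct=d_b,
        d_cbct=d_a,
        opt_g=Adam(g_ab.params() + g_ba.params(), lr=cfg.lr, beta1=0.5),
        opt_d=Adam(d_b.params() + d_a.params(), lr=cfg.disc_rate, beta1=0.5),
        pool_ct=ImagePool(cfg.pool_size, pool_rng),
        pool_cbct=ImagePool(cfg.pool_size, pool_rng),
    )


def _sc_loss(fake: Tensor, source: np.ndarray, cfg: CycleGANConfig) -> Tensor:
    """MIND loss between synthetic slices and their source slices (2D)."""
    b = fake.data.shape[0]
    fake2d = fake.reshape(b, fake.data.shape[2], fake.data.shape[3])
    desc = mind_descriptor(source, cfg.mind, spatial_axes=(1, 2))
    return mind_loss_t(fake2d, desc, cfg.mind, (1, 2))


def cyclegan_step(
    batch_cbct: np.ndarray, batch_ct: np.ndarray, models: CycleGANModels, cfg: CycleGANConfig
) -> dict:
    """One optimization step (generators, then discriminators) on one batch.

    Slices are (B, H, W) in (−1, 1). Returns the loss record with the
    identity ``total = adv + λ·cycle + μ·sc`` holding exactly.
    """
    if batch_cbct.ndim != 3 or batch_ct.ndim != 3:
        raise ValueError("batches must be (B, H, W)")
    if batch_cbct.shape[1:] != batch_ct.shape[1:]:
        raise ValueError(f"slice shape mismatch: {batch_cbct.shape} vs {batch_ct.shape}")
    a = Tensor(batch_cbct[:, None])
    b = Tensor(batch_ct[:, None])

    fake_b = models.g_cbct_ct(a)
    rec_a = models.g_ct_cbct(fake_b)
    fake_a = models.g_ct_cbct(b)
    rec_b = models.g_cbct_ct(fake_a)

    l_adv = _mse_to(models.d_ct(fake_b), 1.0) + _mse_to(models.d_cbct(fake_a), 1.0)
    l_cycle = (rec_a - a).abs().mean() + (rec_b - b).abs().mean()
    l_sc = _sc_loss(fake_b, batch_cbct, cfg) + _sc_loss(fake_a, batch_ct, cfg)
    l_g = l_adv + l_cycle * cfg.lambda_cycle + l_sc * cfg.mu_sc

    models.opt_g.zero_grad()
    models.opt_d.zero_grad()
    l_g.backward()
    models.opt_g.step()

    for _ in range(max(cfg.disc_steps, 1)):
        fb = models.pool_ct.query(fake_b.data.copy())
        fa = models.pool_cbct.query(fake_a.data.copy())
        l_d = (
            _mse_to(models.d_ct(b), 1.0)
            + _mse_to(models.d_ct(Tensor(fb)), 0.0)
            + _mse_to(models.d_cbct(a), 1.0)
            + _mse_to(models.d_cbct(Tensor(fa)), 0.0)
        ) * 0.5
        models.opt_d.zero_grad()
        l_d.backward()
        models.opt_d.step()

    return {
        "adv": float(l_adv.data),
        "cycle": float(l_cycle.data),
        "sc": float(l_sc.data),
        "total": float(l_g.data),
        "disc": float(l_d.data),
    }


def _volume_slices(volumes: list[ImageVolume], divisor: float) -> np.ndarray:
    slices = [normalize_tanh(v, divisor) for v in volumes]
    return np.concatenate([s for s in slices], axis=0).astype(np.float32)


def train_cyclegan(
    volumes_cbct: list[ImageVolume],
    volumes_ct: list[ImageVolume],
    cfg: CycleGANConfig | None = None,
) -> tuple[CycleGANModels, TrainHistory]:
    """Train on axial slices of the given volumes with the stated schedule.

    Domains are treated as unpaired: each epoch shuffles both slice sets
    independently (unless ``paired_batches``), forms batches of ``cfg.batch``
    and runs :func:`cyclegan_step`; the step size follows :func:`scheduled_lr`.
    """
    cfg = cfg or CycleGANConfig()
    slices_a = _volume_slices(volumes_cbct, 400.0)
    slices_b = _volume_slices(volumes_ct, 400.0)
    if slices_a.size == 0 or slices_b.size == 0:
        raise ValueError("empty slice set")
    models = _build_models(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    n = min(len(slices_a), len(slices_b))
    hist = TrainHistory([], [], [], [], [])
    for epoch in range(1, cfg.epochs + 1):
        lr = scheduled_lr(epoch, cfg)
        models.opt_g.lr = lr
        models.opt_d.lr = lr * cfg.disc_rate / cfg.lr if cfg.lr > 0 else cfg.disc_rate
        perm_a = rng.permutation(len(slices_a))[:n]
        perm_b = perm_a if cfg.paired_batches else rng.permutation(len(slices_b))[:n]
        n_epoch = n
        if cfg.steps_per_epoch is not None:
            n_epoch = min(n, cfg.steps_per_epoch * cfg.batch)
        records = []
        for i in range(0, n_epoch - cfg.batch + 1, cfg.batch):
            ba = slices_a[perm_a[i : i + cfg.batch]]
            bb = slices_b[perm_b[i : i + cfg.batch]]
            records.append(cyclegan_step(ba, bb, models, cfg))
        if not records:  # fewer slices than one batch: use them all once
            records.append(cyclegan_step(slices_a[:n], slices_b[:n], models, cfg))
        for key, col in (
            ("adv", hist.adv),
            ("cycle", hist.cycle),
            ("sc", hist.sc),
            ("total", hist.total),
            ("disc", hist.disc),
        ):
            col.append(float(np.mean([r[key] for r in records])))
    return models, hist


def synthesize_ct(generator: GeneratorModel, cbct: ImageVolume, divisor: float = 400.0) -> ImageVolume:
    """CBCT → sCT: tanh-normalize slices, translate, map back to HU."""
    norm = normalize_tanh(cbct, divisor)
    out_norm = generator.apply(norm)
    hu = inverse_tanh(out_norm, divisor)
    return ImageVolume(hu, cbct.spacing, cbct.origin)
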