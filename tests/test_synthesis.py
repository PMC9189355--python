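"""CycleGAN building blocks: shapes, loss identity, schedule, determinism.

Full training behavior (loss descent, MAE improvement on held-out volumes)
is exercised by the acceptance suite; these tests cover the cheap contracts.
"""

import dataclasses

import numpy as np
import pytest

from cbctkit.autodiff import Tensor
from cbctkit.core_io import ImageVolume
from cbctkit.synthesis import (
    CycleGANConfig,
    GeneratorConfig,
    _build_models,
    build_discriminator,
    build_generator,
    cyclegan_step,
    scheduled_lr,
    synthesize_ct,
    train_cyclegan,
)


@pytest.fixture(scope="module")
def tiny_cfg():
    return CycleGANConfig(
        epochs=2,
        decay_epochs=1,
        batch=2,
        generator=GeneratorConfig(base_channels=4, n_resblocks=2),
        pool_size=4,
        seed=7,
    )


def _slices(rng, n=2, h=32, w=32):
    return np.tanh(rng.standard_normal((n, h, w))).astype(np.float32)


class TestGenerators:
    @pytest.mark.parametrize("kind", ["resnet15", "unet5"])
    def test_output_shape_and_range(self, kind, rng):
        gen = build_generator(GeneratorConfig(kind=kind, base_channels=4, n_resblocks=2))
        x = _slices(rng, 2, 96, 128)
        out = gen.apply(x)
        assert out.shape == x.shape
        assert np.all(np.abs(out) < 1.0)

    def test_padding_for_odd_sizes(self, rng):
        gen = build_generator(GeneratorConfig(kind="unet5", base_channels=4))
        out = gen.apply(_slices(rng, 1, 33, 48))
        assert out.shape == (1, 33, 48)

    def test_indivisible_direct_call_rejected(self, rng):
        gen = build_generator(GeneratorConfig(kind="resnet15", base_channels=4, n_resblocks=1))
        with pytest.raises(ValueError):
            gen(Tensor(_slices(rng, 1, 33, 48)[:, None]))

    def test_same_seed_same_parameters(self):
        cfg = GeneratorConfig(base_channels=4, n_resblocks=1, seed=3)
        a, b = build_generator(cfg), build_generator(cfg)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            GeneratorConfig(kind="vgg")


class TestDiscriminator:
    def test_patch_grid_output(self, rng):
        d = build_discriminator(base=4, seed=0)
        out = d(Tensor(_slices(rng, 1, 256, 256)[:, None]))
        assert out.data.shape[2] > 1 and out.data.shape[3] > 1

    def test_deterministic_and_finite_at_extremes(self):
        d = build_discriminator(base=4, seed=0)
        x = np.ones((1, 1, 64, 64), np.float32)
        a = d(Tensor(x)).data
        b = d(Tensor(x)).data
        np.testing.assert_array_equal(a, b)
        assert np.all(np.isfinite(d(Tensor(-x)).data))


class TestStep:
    def test_loss_identity(self, tiny_cfg, rng):
        models = _build_models(tiny_cfg)
        rec = cyclegan_step(_slices(rng), _slices(rng), models, tiny_cfg)
        assert rec["total"] == pytest.approx(
            rec["adv"] + tiny_cfg.lambda_cycle * rec["cycle"] + tiny_cfg.mu_sc * rec["sc"],
            abs=1e-5,
        )

    def test_zero_weights_reduce_to_adversarial(self, rng):
        cfg = CycleGANConfig(
            epochs=1,
            decay_epochs=1,
            lambda_cycle=0.0,
            mu_sc=0.0,
            generator=GeneratorConfig(base_channels=4, n_resblocks=1),
            seed=1,
        )
        models = _build_models(cfg)
        rec = cyclegan_step(_slices(rng), _slices(rng), models, cfg)
        assert rec["total"] == pytest.approx(rec["adv"], abs=1e-6)

    def test_shape_mismatch(self, tiny_cfg, rng):
        models = _build_models(tiny_cfg)
        with pytest.raises(ValueError):
            cyclegan_step(_slices(rng, 2, 32, 32), _slices(rng, 2, 32, 48), models, tiny_cfg)


class TestSchedule:
    def test_constant_then_linear_decay(self):
        cfg = CycleGANConfig(epochs=200, decay_epochs=100, lr=0.002)
        assert scheduled_lr(1, cfg) == pytest.approx(0.002)
        assert scheduled_lr(100, cfg) == pytest.approx(0.002)
        assert scheduled_lr(150, cfg) == pytest.approx(0.001)
        assert scheduled_lr(200, cfg) == pytest.approx(0.0)

    def test_epochs_must_cover_decay(self):
        with pytest.raises(ValueError):
            CycleGANConfig(epochs=50, decay_epochs=100)


class TestTrainAndApply:
    def test_short_training_deterministic(self, tiny_cfg, rng):
        vols_a = [ImageVolume(rng.normal(0, 100, (2, 32, 32)), (5, 2, 2)) for _ in range(2)]
        vols_b = [ImageVolume(rng.normal(40, 80, (2, 32, 32)), (5, 2, 2)) for _ in range(2)]
        _, h1 = train_cyclegan(vols_a, vols_b, tiny_cfg)
        _, h2 = train_cyclegan(vols_a, vols_b, tiny_cfg)
        assert h1.total == h2.total
        assert len(h1.total) == tiny_cfg.epochs
        assert all(np.isfinite(v) for v in h1.total)

    def test_synthesize_preserves_geometry_and_hu_range(self, tiny_cfg, rng):
        models = _build_models(tiny_cfg)
        vol = ImageVolume(rng.normal(0, 200, (3, 32, 32)), (5, 2, 2), origin=(1, 2, 3))
        sct = synthesize_ct(models.g_cbct_ct, vol)
        assert sct.shape == vol.shape
        assert sct.spacing == vol.spacing and sct.origin == vol.origin
        assert sct.voxels.min() >= -1200.0 and sct.voxels.max() <= 1200.0

    def test_empty_slice_set_rejected(self, tiny_cfg):
        with pytest.raises((ValueError, IndexError)):
            train_cyclegan([], [], tiny_cfg)
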