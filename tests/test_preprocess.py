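"""Preprocessing chain: skin mask, air fill, resampling, rigid alignment,
centered cropping and the two normalizations."""

import numpy as np
import pytest

from cbctkit.core_io import AIR_HU, ImageVolume
from cbctkit.metrics import dsc, ncc
from cbctkit.phantom import DegradationSpec, degrade_to_cbct
from cbctkit.preprocess import (
    PreprocessConfig,
    RigidTransform,
    crop_centered,
    crop_offsets,
    desk_config,
    extract_skin_mask,
    fill_outside_body,
    inverse_tanh,
    normalize_registration,
    normalize_tanh,
    resample,
    rigid_align,
)


class TestSkinMask:
    def test_matches_body_label(self, desk_phantom):
        vol, labels = desk_phantom
        mask = extract_skin_mask(vol, desk_config())
        assert dsc(mask, labels.labels > 0) >= 0.98

    def test_couch_excluded(self, desk_phantom):
        vol, labels = desk_phantom
        body = labels.labels > 0
        with_couch = degrade_to_cbct(
            vol, body, DegradationSpec(noise_sd=0, bias_amplitude=0, streak_count=0, couch=True)
        )
        couch_voxels = (with_couch.voxels != vol.voxels) & ~body
        assert couch_voxels.any()
        mask = extract_skin_mask(with_couch, desk_config())
        assert not (mask & couch_voxels).any()

    def test_all_air_rejected(self):
        vol = ImageVolume(np.full((4, 8, 8), -1000.0), spacing=(5, 2, 2))
        with pytest.raises(ValueError):
            extract_skin_mask(vol, desk_config())


class TestFillOutsideBody:
    def test_all_true_mask_is_identity(self, desk_phantom):
        vol, _ = desk_phantom
        out = fill_outside_body(vol, np.ones(vol.shape, bool))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_all_false_mask_gives_air(self, desk_phantom):
        vol, _ = desk_phantom
        out = fill_outside_body(vol, np.zeros(vol.shape, bool))
        assert out.voxels.min() == out.voxels.max() == AIR_HU

    def test_outside_is_exactly_air(self, desk_phantom, rng):
        vol, _ = desk_phantom
        mask = rng.random(vol.shape) > 0.5
        out = fill_outside_body(vol, mask)
        assert np.all(out.voxels[~mask] == AIR_HU)
        np.testing.assert_array_equal(out.voxels[mask], vol.voxels[mask])


class TestResample:
    def test_identity_spacing(self, desk_phantom):
        vol, _ = desk_phantom
        out = resample(vol, vol.spacing)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-6)

    def test_constant_volume_preserved(self):
        vol = ImageVolume(np.full((8, 16, 16), 55.0), spacing=(5, 2, 2))
        out = resample(vol, (5, 1, 1))
        assert out.voxels.shape == (8, 32, 32)
        np.testing.assert_allclose(out.voxels, 55.0, atol=1e-4)

    def test_inplane_upsampling_doubles_dims(self, desk_phantom):
        vol, _ = desk_phantom
        out = resample(vol, (5.0, 1.0, 1.0))
        nz, ny, nx = vol.shape
        assert out.voxels.shape[0] == nz
        assert abs(out.voxels.shape[1] - 2 * ny) <= 1
        assert abs(out.voxels.shape[2] - 2 * nx) <= 1
        assert out.spacing == (5.0, 1.0, 1.0)

    def test_invalid_spacing(self, desk_phantom):
        with pytest.raises(ValueError):
            resample(desk_phantom[0], (0.0, 1.0, 1.0))


class TestRigidAlign:
    def test_self_alignment_is_identity(self, desk_phantom):
        vol, labels = desk_phantom
        skin = labels.labels > 0
        t, aligned = rigid_align(vol, vol, skin, skin, desk_config())
        assert max(abs(np.array(t.translation))) <= 2.0  # one in-plane voxel
        assert abs(t.rotation_deg) <= 1.0

    def test_known_translation_recovered(self, desk_phantom):
        vol, labels = desk_phantom
        cfg = desk_config()
        shifted = ImageVolume(np.roll(vol.voxels, (5, -5), axis=(1, 2)), vol.spacing)
        skin_m = extract_skin_mask(shifted, cfg)
        skin_f = extract_skin_mask(vol, cfg)
        t, aligned = rigid_align(shifted, vol, skin_m, skin_f, cfg)
        # moving = fixed shifted by (+10, -10) mm → transform ≈ (+10, -10) mm
        assert t.translation[1] == pytest.approx(10.0, abs=2.0)
        assert t.translation[2] == pytest.approx(-10.0, abs=2.0)
        assert ncc(vol.voxels, aligned.voxels) > 0.98

    def test_search_only_improves(self, desk_phantom):
        vol, labels = desk_phantom
        cfg = desk_config()
        rng = np.random.default_rng(0)
        noisy = ImageVolume(
            np.roll(vol.voxels, 3, axis=2) + rng.normal(0, 10, vol.shape), vol.spacing
        )
        skin_m = extract_skin_mask(noisy, cfg)
        skin_f = labels.labels > 0
        t, aligned = rigid_align(noisy, vol, skin_m, skin_f, cfg)
        lo, hi = cfg.clip_range
        centroid_only = RigidTransform((0.0, 0.0, 0.0), 0.0)
        from cbctkit.preprocess import _apply_rigid
        from scipy import ndimage

        base = ncc(
            np.clip(vol.voxels, lo, hi),
            np.clip(
                _apply_rigid(noisy, centroid_only, ndimage.center_of_mass(skin_f)), lo, hi
            ),
        )
        assert ncc(np.clip(vol.voxels, lo, hi), np.clip(aligned.voxels, lo, hi)) >= base - 1e-9

    def test_empty_skin_rejected(self, desk_phantom):
        vol, _ = desk_phantom
        empty = np.zeros(vol.shape, bool)
        with pytest.raises(ValueError):
            rigid_align(vol, vol, empty, empty)


class TestCrop:
    def test_output_shape_exact(self, desk_phantom):
        vol, labels = desk_phantom
        out = crop_centered(vol, labels.labels > 0, (64, 96))
        assert out.voxels.shape == (vol.shape[0], 64, 96)

    def test_paper_crop_shape(self, desk_phantom):
        vol, labels = desk_phantom
        out = crop_centered(vol, labels.labels > 0, (288, 400))
        assert out.voxels.shape[1:] == (288, 400)

    def test_already_centered_is_identity(self):
        v = np.zeros((2, 8, 12), np.float32)
        v[:, 4, 6] = 100.0  # centroid exactly at the central voxel (floor convention)
        vol = ImageVolume(v, spacing=(5, 2, 2))
        skin = v > 0
        out = crop_centered(vol, skin, (8, 12))
        np.testing.assert_array_equal(out.voxels, v)

    def test_padding_is_air(self, desk_phantom):
        vol, labels = desk_phantom
        skin = labels.labels > 0
        out = crop_centered(vol, skin, (192, 256))
        assert out.voxels[:, 0, :].max() == AIR_HU

    def test_offsets_reusable_for_labels(self, desk_phantom):
        vol, labels = desk_phantom
        skin = labels.labels > 0
        offs = crop_offsets(skin, (64, 96))
        a = crop_centered(vol, skin, (64, 96))
        b = crop_centered(vol, skin, (64, 96), offsets=offs)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestNormalizations:
    def test_registration_mapping_endpoints(self):
        cfg = PreprocessConfig()
        x = np.array([[[-250.0, 200.0, -25.0, -1000.0, 500.0]]])
        y = normalize_registration(x, cfg)
        np.testing.assert_allclose(y[0, 0], [-1.0, 1.0, 0.0, -1.0, 1.0], atol=1e-6)

    def test_registration_monotone(self, rng):
        x = np.sort(rng.random(100) * 1000 - 500).reshape(1, 10, 10)
        y = normalize_registration(x)
        assert np.all(np.diff(y.ravel()) >= 0)

    def test_tanh_closed_forms(self):
        x = np.array([[[0.0, 400.0]]])
        y = normalize_tanh(x)
        assert y[0, 0, 0] == pytest.approx(0.0)
        assert y[0, 0, 1] == pytest.approx(np.tanh(1.0), abs=1e-6)

    def test_tanh_round_trip_within_half_hu(self):
        hu = np.arange(-1000.0, 1001.0, 1.0, dtype=np.float32).reshape(1, 1, -1)
        back = inverse_tanh(normalize_tanh(hu))
        assert np.abs(back - hu).max() < 0.5

    def test_tanh_strictly_increasing(self, rng):
        x = np.sort(rng.random(50) * 2000 - 1000)
        y = normalize_tanh(x.reshape(1, 1, -1)).ravel()
        assert np.all(np.diff(y) > 0)


class TestConfigValidation:
    def test_bad_clip_range(self):
        with pytest.raises(ValueError):
            PreprocessConfig(clip_range=(200.0, -250.0))

    def test_odd_crop_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(crop_size=(97, 128))
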