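"""Phantom generator: determinism, anatomy, degradation and deformations."""

import numpy as np
import pytest

from cbctkit.core_io import extract_mask
from cbctkit.fields import jacobian_determinant
from cbctkit.metrics import dsc, mask_volume_mm3, volume_diff
from cbctkit.phantom import (
    DeformationSpec,
    DegradationSpec,
    PhantomSpec,
    degrade_to_cbct,
    generate_phantom,
    make_pair,
    sample_deformation,
)


class TestGeneratePhantom:
    def test_seeded_determinism(self, desk_spec):
        v1, l1 = generate_phantom(desk_spec)
        v2, l2 = generate_phantom(desk_spec)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_all_organs_present_and_exclusive(self, desk_phantom):
        _, labels = desk_phantom
        present = set(np.unique(labels.labels))
        assert present == set(labels.organ_table.values()) | {0}
        # labels are a single integer per voxel by construction; check the
        # organ masks rasterized from geometry do not overlap in the label map
        for organ in ("bladder", "spinal_cord", "femoral_head_l"):
            assert extract_mask(labels, organ).any()

    def test_hu_means(self, desk_phantom):
        vol, labels = desk_phantom
        bladder = vol.voxels[extract_mask(labels, "bladder")]
        assert abs(bladder.mean() - 2.0) < 3.0
        outside = vol.voxels[labels.labels == 0]
        assert np.all(outside == -1000.0)

    def test_bladder_scale_cubes_to_volume(self):
        """Linear scale 1.26 ≈ 2× volume (1.26³ ≈ 2.0)."""
        base = PhantomSpec(grid_shape=(16, 96, 128), spacing=(5, 2, 2), seed=5)
        scaled = PhantomSpec(
            grid_shape=(16, 96, 128), spacing=(5, 2, 2), seed=5, bladder_scale=1.26
        )
        _, l1 = generate_phantom(base)
        _, l2 = generate_phantom(scaled)
        ratio = extract_mask(l2, "bladder").sum() / extract_mask(l1, "bladder").sum()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_organ_outside_body_rejected(self):
        spec = PhantomSpec(
            grid_shape=(16, 96, 128),
            spacing=(5, 2, 2),
            cord_center_yx=(200.0, 0.0),  # outside the body ellipse
        )
        with pytest.raises(ValueError):
            generate_phantom(spec)


class TestDegradation:
    def test_zero_spec_is_identity(self, desk_phantom):
        vol, labels = desk_phantom
        spec = DegradationSpec(
            noise_sd=0, bias_amplitude=0, streak_count=0, cavity=False, global_offset=0
        )
        out = degrade_to_cbct(vol, labels.labels > 0, spec)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_noise_sd_calibrated(self, desk_phantom):
        vol, labels = desk_phantom
        body = labels.labels > 0
        assert body.sum() > 10**4
        spec = DegradationSpec(noise_sd=30.0, bias_amplitude=0, streak_count=0, seed=3)
        out = degrade_to_cbct(vol, body, spec)
        sd = (out.voxels - vol.voxels)[body].std()
        assert sd == pytest.approx(30.0, abs=2.0)

    def test_any_degradation_increases_mae(self, desk_phantom):
        vol, labels = desk_phantom
        out = degrade_to_cbct(vol, labels.labels > 0, DegradationSpec(seed=1))
        assert np.abs(out.voxels - vol.voxels).mean() > 0

    def test_shape_mismatch(self, desk_phantom):
        vol, _ = desk_phantom
        with pytest.raises(ValueError):
            degrade_to_cbct(vol, np.ones((2, 2, 2), bool), DegradationSpec())

    def test_determinism(self, desk_phantom):
        vol, labels = desk_phantom
        body = labels.labels > 0
        a = degrade_to_cbct(vol, body, DegradationSpec(seed=9))
        b = degrade_to_cbct(vol, body, DegradationSpec(seed=9))
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestSampleDeformation:
    def test_zero_max_displacement(self):
        f = sample_deformation(DeformationSpec(max_displacement_mm=0), (8, 32, 32), (5, 2, 2))
        assert not f.any()

    def test_seeded_determinism(self):
        spec = DeformationSpec(seed=4)
        a = sample_deformation(spec, (8, 32, 32), (5, 2, 2))
        b = sample_deformation(spec, (8, 32, 32), (5, 2, 2))
        np.testing.assert_array_equal(a, b)

    def test_magnitude_bound_and_boundary_band(self):
        spec = DeformationSpec(max_displacement_mm=12.0, seed=7)
        f = sample_deformation(spec, (16, 96, 128), (5, 2, 2))
        mm = f * np.array([5.0, 2.0, 2.0])
        norms = np.sqrt((mm**2).sum(-1))
        assert norms.max() == pytest.approx(12.0, rel=1e-4)
        assert np.abs(f[0]).max() == 0 and np.abs(f[-1]).max() == 0

    def test_positive_jacobian_for_gentle_fields(self):
        """Max displacement below a third of the control spacing stays invertible."""
        spec = DeformationSpec(
            control_spacing_mm=(25, 48, 48), max_displacement_mm=16.0, seed=2
        )
        f = sample_deformation(spec, (16, 96, 128), (5, 2, 2))
        det = jacobian_determinant(f)
        assert (det > 0).mean() >= 0.99

    def test_control_spacing_validation(self):
        with pytest.raises(ValueError):
            sample_deformation(
                DeformationSpec(control_spacing_mm=(2.0, 40, 40)), (8, 32, 32), (5, 2, 2)
            )


class TestMakePair:
    def test_null_pair_is_identical(self, desk_spec):
        pair = make_pair(
            desk_spec,
            DegradationSpec(noise_sd=0, bias_amplitude=0, streak_count=0),
            DeformationSpec(max_displacement_mm=0),
            bladder_diff_target=0.0,
        )
        np.testing.assert_array_equal(pair.cbct.voxels, pair.pct.voxels)
        np.testing.assert_array_equal(pair.cbct_labels.labels, pair.pct_labels.labels)
        assert not pair.true_field.any()

    def test_diff_target_hit_within_tolerance(self, desk_spec):
        pair = make_pair(
            desk_spec, DegradationSpec(seed=2), DeformationSpec(seed=3), bladder_diff_target=100.0
        )
        v_c = mask_volume_mm3(extract_mask(pair.cbct_labels, "bladder"), desk_spec.spacing)
        v_p = mask_volume_mm3(extract_mask(pair.pct_labels, "bladder"), desk_spec.spacing)
        assert 90.0 <= volume_diff(v_c, v_p) <= 110.0
        assert pair.achieved_bladder_diff == pytest.approx(volume_diff(v_c, v_p))

    def test_body_outline_stable(self, small_pair):
        body_p = extract_mask(small_pair.pct_labels, "body") | (small_pair.pct_labels.labels > 0)
        body_c = small_pair.cbct_labels.labels > 0
        assert dsc(body_p, body_c) >= 0.95

    def test_diff_monotone_in_scale(self, desk_spec):
        diffs = []
        for target in (20.0, 60.0, 150.0):
            pair = make_pair(
                desk_spec, DegradationSpec(seed=2), DeformationSpec(seed=3), target
            )
            diffs.append(pair.achieved_bladder_diff)
        assert diffs == sorted(diffs)

    def test_same_seeds_identical(self, desk_spec):
        a = make_pair(desk_spec, DegradationSpec(seed=2), DeformationSpec(seed=3), 30.0)
        b = make_pair(desk_spec, DegradationSpec(seed=2), DeformationSpec(seed=3), 30.0)
        np.testing.assert_array_equal(a.cbct.voxels, b.cbct.voxels)
        np.testing.assert_array_equal(a.true_field, b.true_field)

    def test_unreachable_target(self, desk_spec):
        with pytest.raises(ValueError):
            make_pair(desk_spec, DegradationSpec(), DeformationSpec(), 500.0)
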