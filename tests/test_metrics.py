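"""Metric implementations against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbctkit.metrics import (
    MetricsConfig,
    dsc,
    error_metrics,
    ncc,
    nmi,
    ssim,
    ssim_global,
    volume_diff,
)

import oracles


class TestDSC:
    def test_identity(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        assert dsc(a, a) == 1.0

    def test_closed_form_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :8].flat[:8] = True
        a = np.zeros((4, 4, 4), bool)
        a.flat[:8] = True
        b.flat[4:12] = True
        assert dsc(a, b) == pytest.approx(0.5)

    def test_disjoint_and_empty(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dsc(a, b) == 0.0
        empty = np.zeros((3, 3, 3), bool)
        assert dsc(empty, empty) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((3, 2, 2), bool))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_in_intersection(self, seed):
        """Growing |a∩b| at fixed |a|+|b| never decreases DSC."""
        r = np.random.default_rng(seed)
        a = r.random((5, 5, 5)) > 0.5
        b = r.random((5, 5, 5)) > 0.5
        base = dsc(a, b)
        # move one voxel of b onto a voxel of a\b, keeping |b| constant
        only_b = np.logical_and(b, ~a)
        only_a = np.logical_and(a, ~b)
        if only_b.any() and only_a.any():
            b2 = b.copy()
            b2[tuple(np.argwhere(only_b)[0])] = False
            b2[tuple(np.argwhere(only_a)[0])] = True
            assert dsc(a, b2) >= base


class TestNCC:
    def test_self_and_affine(self, rng):
        x = rng.standard_normal((8, 8, 8))
        assert ncc(x, x) == pytest.approx(1.0, abs=1e-9)
        assert ncc(x, 3.0 * x + 7.0) == pytest.approx(1.0, abs=1e-9)
        assert ncc(x, -2.0 * x + 1.0) == pytest.approx(-1.0, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            ncc(np.ones((4, 4, 4)), np.random.default_rng(0).random((4, 4, 4)))

    def test_matches_loop_oracle(self, rng):
        a = rng.standard_normal((8, 8, 8))
        b = a + 0.5 * rng.standard_normal((8, 8, 8))
        assert ncc(a, b) == pytest.approx(oracles.ncc_loops(a, b), abs=1e-12)


class TestNMI:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((12, 12, 12)) * 1000 - 500
        assert nmi(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_independent_images_near_zero(self):
        r = np.random.default_rng(7)
        cfg = MetricsConfig(nmi_bins=16, nmi_range=(0.0, 1.0))
        a = r.random(10**5).reshape(50, 50, 40)
        b = r.random(10**5).reshape(50, 50, 40)
        assert nmi(a, b, cfg) < 0.02

    def test_matches_loop_oracle(self, rng):
        cfg = MetricsConfig(nmi_bins=8, nmi_range=(-100.0, 100.0))
        a = rng.standard_normal((16, 16, 16)) * 40
        b = a + rng.standard_normal((16, 16, 16)) * 20
        expected = oracles.nmi_loops(a, b, 8, -100.0, 100.0)
        assert nmi(a, b, cfg) == pytest.approx(expected, abs=1e-12)

    def test_constant_image_rejected(self, rng):
        with pytest.raises(ValueError):
            nmi(np.full((4, 4, 4), 3.0), rng.random((4, 4, 4)))


class TestErrorMetrics:
    def test_constant_offset(self, rng):
        a = rng.random((6, 6, 6)) * 100
        mae, rmse, _ = error_metrics(a, a + 10.0)
        assert mae == pytest.approx(10.0, abs=1e-9)
        assert rmse == pytest.approx(10.0, abs=1e-9)

    def test_psnr_closed_form(self):
        """MAX=1000 with RMSE=100 gives exactly 20 dB."""
        a = np.zeros((2, 10, 10))
        a[0, 0, 0] = 1000.0
        b = a + 100.0
        _, rmse, psnr = error_metrics(a, b)
        assert rmse == pytest.approx(100.0)
        assert psnr == pytest.approx(20.0, abs=1e-9)

    def test_identical_images_psnr_infinite(self, rng):
        a = rng.random((4, 4, 4))
        assert error_metrics(a, a)[2] == float("inf")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rmse_dominates_mae(self, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal((5, 5, 5))
        b = r.standard_normal((5, 5, 5))
        mae, rmse, _ = error_metrics(a, b)
        assert rmse >= mae - 1e-12

    def test_matches_loop_oracle(self, rng):
        a = rng.random((8, 8, 8)) * 500
        b = a + rng.standard_normal((8, 8, 8)) * 30
        got = error_metrics(a, b)
        want = oracles.error_metrics_loops(a, b)
        assert got == pytest.approx(want, abs=1e-9)


class TestSSIM:
    def test_self_similarity(self, rng):
        a = rng.random((3, 16, 16)) * 200
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_structure_negative(self, rng):
        a = rng.standard_normal((2, 24, 24)) * 100
        a -= a.mean()
        assert ssim(a, -a) < 0

    def test_global_variant_constant_pair(self):
        assert ssim_global(np.full((3, 4, 4), 5.0), np.full((3, 4, 4), 5.0)) == pytest.approx(1.0)

    def test_window_larger_than_image(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((2, 6, 6)), rng.random((2, 6, 6)))

    def test_matches_loop_oracle(self, rng):
        cfg = MetricsConfig(ssim_window=5)
        a = rng.random((2, 10, 10)) * 100
        b = a + rng.standard_normal((2, 10, 10)) * 10
        expected = oracles.ssim_loops(a, b, 5, cfg.ssim_k1, cfg.ssim_k2)
        assert ssim(a, b, cfg) == pytest.approx(expected, abs=1e-9)


class TestVolumeDiff:
    @pytest.mark.parametrize(
        "va, vb, expected",
        [(150.0, 100.0, 50.0), (100.0, 100.0, 0.0), (210.0, 100.0, 110.0), (100.0, 210.0, 110.0)],
    )
    def test_closed_form(self, va, vb, expected):
        assert volume_diff(va, vb) == pytest.approx(expected)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            volume_diff(0.0, 10.0)


class TestSymmetry:
    def test_symmetric_metrics(self, rng):
        a = rng.random((8, 8, 8)) * 300
        b = a + rng.standard_normal((8, 8, 8)) * 40
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)
        assert ncc(a, b) == pytest.approx(ncc(b, a), abs=1e-12)
        assert error_metrics(a, b)[0] == pytest.approx(error_metrics(b, a)[0], abs=1e-12)
        assert error_metrics(a, b)[1] == pytest.approx(error_metrics(b, a)[1], abs=1e-12)
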