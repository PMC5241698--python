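"""Reconstruction, FRC, extrapolation, density estimators and subsampling."""

import math

import numpy as np
import pandas as pd
import pytest

import smlmkit as sk
from smlmkit.evaluate import frc_curve_from_images


def table_from_points(pts, frames=None):
    pts = np.asarray(pts, dtype=float)
    return pd.DataFrame(
        {
            "frame": np.zeros(len(pts), dtype=int) if frames is None else frames,
            "x_nm": pts[:, 0],
            "y_nm": pts[:, 1],
        }
    )


class TestRenderReconstruction:
    def test_floor_division_convention(self):
        img, origin = sk.render_reconstruction(
            table_from_points([[105.0, 42.0]]), pixel_nm=10.0, bounds=(0, 0, 200, 200)
        )
        assert origin == (0.0, 0.0)
        assert img[4, 10] == 1  # row = y pixel 4, col = x pixel 10
        assert img.sum() == 1

    def test_sum_equals_table_length(self):
        rng = np.random.default_rng(0)
        pts = rng.random((500, 2)) * 1000
        img, _ = sk.render_reconstruction(table_from_points(pts), pixel_nm=10.0)
        assert img.sum() == 500

    def test_empty_table_warns_zero_image(self):
        with pytest.warns(UserWarning):
            img, _ = sk.render_reconstruction(table_from_points(np.empty((0, 2))))
        assert img.sum() == 0


class TestFRC:
    def test_identical_halves_unity(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(3.0, (64, 64)).astype(float)
        frc = frc_curve_from_images(img, img)
        assert np.allclose(frc[frc != 0], 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        im1 = rng.poisson(3.0, (256, 256)).astype(float)
        im2 = rng.poisson(3.0, (256, 256)).astype(float)
        frc = frc_curve_from_images(im1, im2)
        # rings with >= 100 Fourier samples: |FRC| fluctuates at 1/sqrt(n)
        ring_n = 2 * np.pi * np.arange(len(frc))
        sel = (ring_n >= 100) & (np.arange(len(frc)) <= 128)
        assert np.abs(frc[sel]).mean() < 0.05
        assert np.all(np.abs(frc[sel]) < 4.0 / np.sqrt(ring_n[sel]))

    def test_resolution_improves_with_smaller_error(self):
        # cluster structure (broad continuous spectrum) + Gaussian
        # localization error: FRC resolution improves monotonically as the
        # error shrinks
        rng = np.random.default_rng(3)
        centers = rng.random((400, 2)) * 3000
        base = np.repeat(centers, 15, axis=0) + rng.normal(0, 10, (400 * 15, 2))
        res = []
        for sig in (40.0, 20.0, 10.0, 5.0):
            pts = base + rng.normal(0, sig, base.shape)
            out = sk.frc_resolution(table_from_points(pts), n_splits=20, rng_seed=4)
            assert out.resolved
            res.append(out.resolution_nm)
        assert res[0] > res[1] > res[2] > res[3]

    def test_split_swap_symmetric(self):
        rng = np.random.default_rng(5)
        im1 = rng.poisson(2.0, (64, 64)).astype(float)
        im2 = rng.poisson(2.0, (64, 64)).astype(float)
        assert np.allclose(
            frc_curve_from_images(im1, im2), frc_curve_from_images(im2, im1)
        )

    def test_small_table_warns(self):
        rng = np.random.default_rng(6)
        pts = rng.random((50, 2)) * 500
        with pytest.warns(UserWarning, match="variance"):
            sk.frc_resolution(table_from_points(pts), n_splits=3, rng_seed=0)


class TestFramesToQuality:
    def test_arithmetic_example(self):
        # 10 locs/frame on 1e4 nm^2 at Q = 1/25 nm^-2 -> 40 frames
        assert sk.frames_to_quality(10.0, 1e4, 1 / 25) == pytest.approx(40.0)

    def test_linear_in_target(self):
        f1 = sk.frames_to_quality(3.0, 5e4, 0.01)
        f2 = sk.frames_to_quality(3.0, 5e4, 0.02)
        assert f2 == pytest.approx(2 * f1)

    def test_zero_rate_unreachable(self):
        assert sk.frames_to_quality(0.0, 1e4, 0.04) == math.inf


class TestActivationDensity:
    def test_counts_estimator(self):
        table = table_from_points(np.zeros((1000, 2)))
        a = sk.activation_density_from_counts(table, 5.56e6, 1000)
        assert a * 1e6 == pytest.approx(0.18, abs=0.001)

    def test_zero_locs(self):
        table = table_from_points(np.empty((0, 2)))
        assert sk.activation_density_from_counts(table, 1e6, 100) == 0.0

    def test_brightness_proxy_counts_merged_fits(self):
        # n equal-brightness fits -> n; a merged 2x-brightness fit adds 2
        assert sk.activation_proxy_from_brightness([450.0] * 7, 450.0) == pytest.approx(7)
        assert sk.activation_proxy_from_brightness([450.0, 900.0], 450.0) == pytest.approx(3)
        assert sk.activation_proxy_from_brightness([], 450.0) == 0.0

    def test_proxy_exceeds_count_with_merges(self):
        intensities = np.array([450.0] * 50 + [900.0] * 10)
        proxy = sk.activation_proxy_from_brightness(intensities, 450.0)
        assert proxy > len(intensities)


class TestSampleArea:
    def test_solid_blob_area(self):
        img = np.zeros((100, 100))
        img[20:70, 10:60] = 3
        area = sk.estimate_sample_area(img, pixel_nm=10.0)
        assert area == pytest.approx(2500 * 100)  # 0.25 um^2

    def test_small_clusters_removed(self):
        img = np.zeros((50, 50))
        for i in range(9):  # 9 isolated single pixels
            img[5 * i + 1, 5 * i + 1] = 1
        with np.errstate(all="ignore"):
            assert sk.estimate_sample_area(img, 10.0) == 0.0

    def test_ten_pixel_boundary(self):
        img = np.zeros((50, 50))
        img[5, 10:20] = 1  # 10-pixel cluster: survives
        img[30, 10:19] = 1  # 9-pixel cluster: removed
        assert sk.estimate_sample_area(img, 10.0) == pytest.approx(10 * 100)


class TestSubsampleFrames:
    def test_identity_when_all_requested(self):
        table = table_from_points(np.zeros((100, 2)), frames=np.arange(100))
        out = sk.subsample_frames(table, 90, trim_head=0.05, trim_tail=0.05)
        assert sorted(out["frame"]) == list(range(5, 95))

    def test_seed_reproducible(self):
        table = table_from_points(np.zeros((200, 2)), frames=np.arange(200))
        o1 = sk.subsample_frames(table, 50, rng_seed=3)
        o2 = sk.subsample_frames(table, 50, rng_seed=3)
        assert o1.equals(o2)

    def test_over_request_rejected(self):
        table = table_from_points(np.zeros((100, 2)), frames=np.arange(100))
        with pytest.raises(ValueError, match="after trimming"):
            sk.subsample_frames(table, 95)

    def test_sampled_frames_uniform(self):
        table = table_from_points(np.zeros((1000, 2)), frames=np.arange(1000))
        from scipy import stats

        rejections = 0
        for seed in range(20):
            out = sk.subsample_frames(table, 200, rng_seed=seed)
            u = (out["frame"].to_numpy() - 50) / 900.0
            if stats.kstest(u, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_stack_subsampling(self):
        stack = sk.FrameStack(np.arange(40).reshape(10, 2, 2).astype(float), 110.0)
        out = sk.subsample_frames(stack, 4, rng_seed=0, trim_head=0.1, trim_tail=0.1)
        assert out.n_frames == 4
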