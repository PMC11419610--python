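import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexdetect.enhancement import (BemParams, ClaheParams, boundary_channel,
                                    clahe, clip_redistribute,
                                    clip_threshold_from_slope, enhance,
                                    global_he, rms_contrast, tile_mapping)
from flexdetect.synthetic import SceneSpec, generate_scene


class TestClipRedistribute:
    def test_toy_four_bins(self):
        out = clip_redistribute(np.array([10.0, 0, 0, 0]), 4.0)
        assert out == pytest.approx([5.5, 1.5, 1.5, 1.5])
        assert out.sum() == pytest.approx(10.0, abs=1e-9)

    def test_all_below_threshold_unchanged(self):
        h = np.array([1.0, 2.0, 3.0, 0.5])
        assert clip_redistribute(h, 10.0) == pytest.approx(h)

    def test_uniform_at_threshold(self):
        h = np.full(8, 3.0)
        assert clip_redistribute(h, 3.0) == pytest.approx(h)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            clip_redistribute(np.ones(4), 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_mass_conserved_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 50, size=256)
        t = rng.uniform(0.5, 40)
        out = clip_redistribute(h, t)
        assert out.sum() == pytest.approx(h.sum(), abs=1e-9)
        assert (out >= 0).all()


class TestClipThreshold:
    def test_worked_values(self):
        assert clip_threshold_from_slope(2, 16) == pytest.approx(512 / 255)
        assert clip_threshold_from_slope(4, 8) == pytest.approx(256 / 255)

    def test_inverse_identity(self):
        m = 12
        assert clip_threshold_from_slope(255 / m ** 2, m) == pytest.approx(1.0)


class TestTileMapping:
    def test_round_half_up_at_midpoint(self):
        # 64-pixel window, CDF = 32 at level 0: m = round(255*32/64) = 128
        h = np.zeros(256)
        h[0] = 32
        h[255] = 32
        lut = tile_mapping(h)
        assert lut[0] == 128  # 127.5 rounds up
        assert lut[255] == 255

    def test_degenerate_single_level(self):
        h = np.zeros(256)
        h[0] = 10
        assert tile_mapping(h)[0] == 255

    def test_uniform_histogram_near_identity(self):
        lut = tile_mapping(np.ones(256))
        assert np.abs(lut.astype(int) - np.arange(1, 257).clip(0, 255)).max() <= 1

    def test_monotone_non_decreasing(self, rng):
        for _ in range(20):
            lut = tile_mapping(rng.uniform(0, 5, 256))
            assert (np.diff(lut.astype(int)) >= 0).all()

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            tile_mapping(np.zeros(256))


class TestClahe:
    def test_single_tile_unclipped_equals_global_he(self):
        for seed in range(20):
            img, _ = generate_scene(SceneSpec(height=64, width=64), seed=seed)
            a = clahe(img, ClaheParams(1, 1, s_max=None)).astype(int)
            b = global_he(img).astype(int)
            assert np.abs(a - b).max() <= 1

    def test_constant_image_constant_output(self):
        img = np.full((32, 32, 3), 77, np.uint8)
        out = clahe(img, ClaheParams(4, 4))
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_low_contrast_rms_increases(self, low_contrast_image):
        before = rms_contrast(low_contrast_image)
        after = rms_contrast(clahe(low_contrast_image))
        assert after > before

    def test_image_smaller_than_grid_rejected(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((4, 4, 3), np.uint8), ClaheParams(8, 8))

    def test_per_channel_mode_runs(self, low_contrast_image):
        out = clahe(low_contrast_image, ClaheParams(4, 4, channel_mode="per_channel"))
        assert out.shape == low_contrast_image.shape


class TestGlobalHE:
    def test_constant_image(self):
        img = np.full((16, 16, 3), 90, np.uint8)
        out = global_he(img)
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_two_level_image_mapping(self):
        # equal halves at luma 50 and 200 -> CDF steps at 0.5 and 1.0
        img = np.zeros((10, 10, 3), np.uint8)
        img[:, :5] = 50
        img[:, 5:] = 200
        out = global_he(img).astype(float)
        luma = out @ np.array([0.299, 0.587, 0.114])
        levels = np.unique(np.rint(luma))
        assert set(levels.astype(int)) == {128, 255}


class TestBoundaryChannel:
    def test_constant_image_zero_map(self):
        img = np.full((32, 32, 3), 120, np.uint8)
        assert boundary_channel(img).max() == 0.0

    def test_step_edge_peaks_on_step(self):
        img = np.zeros((40, 40, 3), np.uint8)
        img[:, 20:] = 200
        b = boundary_channel(img, BemParams(fine_scale_radius=0))
        peak_cols = np.argmax(b, axis=1)
        assert np.all((peak_cols >= 19) & (peak_cols <= 21))
        assert b[:, :10].max() == 0.0 and b[:, 30:].max() == 0.0

    def test_fine_checkerboard_suppressed_by_coarse_mask(self):
        # period-2 checkerboard vanishes under 4x block averaging
        tile = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        board = np.tile(tile, (20, 20))
        img = np.dstack([board] * 3)
        b = boundary_channel(img, BemParams(coarse_downsample=4))
        assert b.mean() < 0.01


class TestEnhance:
    def test_gamma_zero_equals_clahe(self, low_contrast_image):
        p = ClaheParams(4, 4)
        a = enhance(low_contrast_image, p, BemParams(fusion_weight=0.0))
        b = clahe(low_contrast_image, p)
        assert np.array_equal(a, b)

    def test_constant_image_constant_output(self):
        img = np.full((32, 32, 3), 140, np.uint8)
        out = enhance(img, ClaheParams(4, 4))
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_deterministic(self, scene_pair):
        img, _ = scene_pair
        assert np.array_equal(enhance(img), enhance(img))

    def test_rms_contrast_increases_on_degraded_scenes(self):
        for seed in range(20):
            img, _ = generate_scene(SceneSpec(), seed=seed)
            assert rms_contrast(enhance(img)) > rms_contrast(img)

    def test_boundary_band_gradient_energy_increases(self):
        from flexdetect.enhancement import _gradient_magnitude, _RGB2YCBCR

        def band_energy(img, boxes):
            gray = img.astype(float) @ _RGB2YCBCR[0]
            grad = _gradient_magnitude(gray)
            h, w = gray.shape
            band = np.zeros((h, w), bool)
            for b in boxes:
                x1, y1, x2, y2 = b.to_pixels(w, h)
                for (xa, ya, xb, yb) in [(x1, y1, x2, y1), (x1, y2, x2, y2),
                                         (x1, y1, x1, y2), (x2, y1, x2, y2)]:
                    xs = np.clip(np.arange(int(xa) - 3, int(xb) + 4), 0, w - 1)
                    ys = np.clip(np.arange(int(ya) - 3, int(yb) + 4), 0, h - 1)
                    band[np.ix_(ys, xs)] = True
            return grad[band].mean()

        improved = 0
        for seed in range(10):
            img, boxes = generate_scene(SceneSpec(), seed=seed)
            if not boxes:
                continue
            if band_energy(enhance(img), boxes) > band_energy(img, boxes):
                improved += 1
        assert improved >= 8
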