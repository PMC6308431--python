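import numpy as np
import pytest

from blastograde import imaging, rescale as rsc, segmentation as seg, synthetic
from .conftest import make_ring


class TestEqualizeHistogram:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 99, dtype=np.uint8)
        np.testing.assert_array_equal(rsc.equalize_histogram(img), img)

    def test_two_extreme_values_unchanged(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[16:] = 255
        np.testing.assert_array_equal(rsc.equalize_histogram(img), img)

    def test_linear_ramp_near_identity(self):
        # uniform histogram: the CDF mapping is close to the identity
        img = np.tile(np.arange(256, dtype=np.uint8), (8, 1))
        out = rsc.equalize_histogram(img)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 2

    def test_output_range(self):
        rng = np.random.default_rng(0)
        img = rng.integers(100, 130, (40, 40), dtype=np.uint8)
        out = rsc.equalize_histogram(img)
        assert out.min() >= 0 and out.max() <= 255


class TestContrastMagnifyBinarize:
    def test_bright_object_becomes_foreground(self):
        rng = np.random.default_rng(1)
        img = rng.normal(40, 5, (200, 200)).clip(0, 255).astype(np.uint8)
        rr, cc = np.mgrid[0:200, 0:200]
        obj = (rr - 100) ** 2 + (cc - 100) ** 2 <= 30 ** 2
        img[obj] = 220
        binary = rsc.contrast_magnify_binarize(img)
        assert binary[obj].mean() > 0.9
        assert binary[~obj].mean() < 0.05

    def test_constant_image_all_false(self):
        assert not rsc.contrast_magnify_binarize(np.full((50, 50), 120, np.uint8)).any()

    def test_inverted_polarity_normalized(self):
        # dark object on bright background: foreground is still the object
        rng = np.random.default_rng(2)
        img = rng.normal(220, 5, (200, 200)).clip(0, 255).astype(np.uint8)
        rr, cc = np.mgrid[0:200, 0:200]
        obj = (rr - 100) ** 2 + (cc - 100) ** 2 <= 30 ** 2
        img[obj] = 30
        binary = rsc.contrast_magnify_binarize(img)
        assert binary[obj].mean() > 0.9


class TestVariableRangeHough:
    @pytest.mark.parametrize("radius,window", [(15, (8, 20)), (60, (45, 75))])
    def test_small_circle_detected_in_window(self, radius, window):
        binary = np.zeros((480, 640), bool)
        rr, cc = np.mgrid[0:480, 0:640]
        binary[(rr - 240) ** 2 + (cc - 320) ** 2 <= radius ** 2] = True
        det = rsc.variable_range_hough(binary)
        assert det is not None
        assert abs(det.radius - radius) <= 3
        assert window[0] <= det.radius <= window[1] + 3

    def test_blank_absent(self):
        assert rsc.variable_range_hough(np.zeros((100, 100), bool)) is None


class TestWatershedFallback:
    def test_circular_blob_beats_elongated(self):
        binary = np.zeros((200, 300), bool)
        rr, cc = np.mgrid[0:200, 0:300]
        disk = (rr - 100) ** 2 + (cc - 80) ** 2 <= 30 ** 2
        bar = (np.abs(rr - 100) <= 8) & (cc >= 110) & (cc <= 260)
        binary |= disk | bar
        mask = rsc.watershed_fallback(binary)
        assert mask is not None
        assert (mask & disk).sum() / disk.sum() > 0.8
        assert (mask & bar).sum() / bar.sum() < 0.2

    def test_empty_foreground_absent(self):
        assert rsc.watershed_fallback(np.zeros((50, 50), bool)) is None

    def test_single_disk_high_circularity(self):
        binary = np.zeros((200, 200), bool)
        rr, cc = np.mgrid[0:200, 0:200]
        disk = (rr - 100) ** 2 + (cc - 100) ** 2 <= 40 ** 2
        binary |= disk
        mask = rsc.watershed_fallback(binary)
        assert mask is not None
        inter = (mask & disk).sum()
        union = (mask | disk).sum()
        assert inter / union > 0.9


class TestBicubicExpand:
    def test_constant_stays_constant(self):
        out = rsc.bicubic_expand(np.full((20, 20), 77.0), (0, 0, 20, 20), 3.0)
        assert np.all(out == 77)

    def test_exact_on_cubic_polynomial_surface(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(size=(4, 4))

        def poly(r, c):
            return sum(coef[i, j] * (r / 10) ** i * (c / 10) ** j
                       for i in range(4) for j in range(4))

        h = w = 30
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        src = poly(rr, cc)
        scale = 2.5
        out = rsc.bicubic_expand(src, (0, 0, h, w), scale, clip=False)
        orr = (np.arange(out.shape[0]) + 0.5) / scale - 0.5
        occ = (np.arange(out.shape[1]) + 0.5) / scale - 0.5
        sel_r = (orr >= 1) & (orr <= h - 3)  # interior: no border clamping
        sel_c = (occ >= 1) & (occ <= w - 3)
        expected = poly(orr[sel_r][:, None], occ[sel_c][None, :])
        assert np.abs(out[np.ix_(sel_r, sel_c)] - expected).max() <= 1e-6

    def test_output_geometry(self):
        src = np.random.default_rng(1).uniform(0, 255, (120, 120))
        out = rsc.bicubic_expand(src, (10, 10, 110, 110), 2.0)
        assert out.shape == (200, 200)

    def test_patch_reproduces_constraints(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(size=(4, 4))
        patch = rsc.BicubicPatch(samples)
        nodes = [-1.0, 0.0, 1.0, 2.0]
        for i, x in enumerate(nodes):
            for j, y in enumerate(nodes):
                assert patch.evaluate(x, y) == pytest.approx(samples[i, j], abs=1e-9)

    def test_patch_matches_separable_path(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 255, (8, 8))
        out = rsc.bicubic_expand(src, (0, 0, 8, 8), 2.0, clip=False)
        # output sample (7, 9) maps to source (3.25, 4.25): stencil [2:6, 3:7]
        patch = rsc.BicubicPatch(src[2:6, 3:7])
        assert out[7, 9] == pytest.approx(patch.evaluate(0.25, 0.25), abs=1e-9)

    def test_tiny_crop_rejected(self):
        with pytest.raises(rsc.CropError):
            rsc.bicubic_expand(np.zeros((20, 20)), (0, 0, 4, 4), 2.0)


class TestRescaleImage:
    @pytest.mark.parametrize("regime,seed", [("smartphone_d1", 0), ("smartphone_d2", 3)])
    def test_small_embryo_expanded_into_main_window(self, regime, seed):
        raw, truth = synthetic.render_blastocyst(
            synthetic.SyntheticSpec(regime=regime, seed=seed))
        res = rsc.rescale_image(raw)
        assert res.found_by == "hough_variable_range"
        assert res.scale_factor > 1
        det = seg.detect_circle(res.output)
        assert det is not None
        assert 100 <= det.radius <= 200

    def test_noise_not_found(self):
        hits = 0
        for s in range(20):
            g = np.random.default_rng(500 + s).normal(128, 20, (480, 640))
            g = g.clip(0, 255).astype(np.uint8)
            if rsc.rescale_image(g).found_by != "not_found":
                hits += 1
        assert hits == 0

    def test_scale_capped(self):
        raw, _ = synthetic.render_blastocyst(
            synthetic.SyntheticSpec(regime="smartphone_d2", seed=1))
        res = rsc.rescale_image(raw)
        assert res.scale_factor <= rsc.MAX_SCALE
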