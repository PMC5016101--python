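import numpy as np
import pytest
from scipy import ndimage as ndi

from peroxiquant.morphology import (
    circle_reference,
    clean_mask,
    erode,
    measure_clusters,
    region_cluster_shapes,
    threshold_max_entropy,
)

from _oracles import exhaustive_max_entropy_bin


def _disc(diameter):
    r = diameter // 2
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1]
    return ys**2 + xs**2 <= (diameter / 2.0) ** 2


class TestMaxEntropyThreshold:
    def test_two_level_patch_separates_levels(self):
        patch = np.full((10, 10), 50.0)
        patch.ravel()[:10] = 200.0
        t = threshold_max_entropy(patch)
        assert 50.0 < t < 200.0

    def test_matches_exhaustive_entropy_oracle(self, rng):
        """Vectorized threshold equals exhaustive 256-candidate search."""
        for _ in range(50):
            patch = rng.integers(0, 256, size=(15, 15)).astype(float)
            t = threshold_max_entropy(patch)
            t_bin = exhaustive_max_entropy_bin(patch)
            vmin, vmax = patch.min(), patch.max()
            expected = vmin + (t_bin + 0.5) * (vmax - vmin) / 255.0
            np.testing.assert_allclose(t, expected, rtol=1e-12)

    def test_constant_patch_is_an_error(self):
        with pytest.raises(ValueError, match="flat region"):
            threshold_max_entropy(np.full((8, 8), 3.0))


class TestCleanMask:
    def test_isolated_pixel_removed_by_despeckle(self):
        m = np.zeros((15, 15), bool)
        m[7, 7] = True
        assert not clean_mask(m).any()

    def test_erode_square_shrinks_by_one(self):
        m = np.zeros((15, 15), bool)
        m[4:11, 4:11] = True  # 7×7
        out = erode(m)
        expected = np.zeros_like(m)
        expected[5:10, 5:10] = True  # 5×5
        np.testing.assert_array_equal(out, expected)

    def test_full_chain_matches_independent_scipy_oracle(self):
        m = np.zeros((15, 15), bool)
        m[4:11, 4:11] = True
        out = clean_mask(m)
        oracle = ndi.binary_erosion(
            ndi.median_filter(m.astype(np.uint8), size=3, mode="constant", cval=0) > 0,
            structure=np.ones((3, 3), bool),
            border_value=0,
        )
        np.testing.assert_array_equal(out, oracle)

    def test_empty_mask_passes_through(self):
        assert not clean_mask(np.zeros((9, 9), bool)).any()


class TestMeasureClusters:
    def test_single_pixel(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        (c,) = measure_clusters(m)
        assert (c.area_px, c.perimeter_px) == (1, 1)

    def test_filled_5x5_square(self):
        m = np.zeros((11, 11), bool)
        m[3:8, 3:8] = True
        (c,) = measure_clusters(m)
        assert (c.area_px, c.perimeter_px) == (25, 16)

    def test_digital_disc_close_to_circle_reference(self):
        d = 21
        m = np.zeros((31, 31), bool)
        r = 15
        ys, xs = np.mgrid[0:31, 0:31]
        m[(ys - r) ** 2 + (xs - r) ** 2 <= (d / 2.0) ** 2] = True
        (c,) = measure_clusters(m)
        perim_ref, area_ref = circle_reference(d)
        # joint (perimeter, area) comparison: the boundary-pixel perimeter of
        # a rasterized disc sits systematically below πd, but the measured
        # point stays within 15% of the reference point
        err = np.hypot(c.perimeter_px - perim_ref, c.area_px - area_ref)
        assert err / np.hypot(perim_ref, area_ref) < 0.15
        assert abs(c.area_px - area_ref) / area_ref < 0.15

    def test_touching_diagonal_pixels_are_one_cluster(self):
        m = np.zeros((6, 6), bool)
        m[1, 1] = m[2, 2] = True
        assert len(measure_clusters(m)) == 1

    def test_nm_conversion(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        (c,) = measure_clusters(m, pixel_size_nm=20.0)
        assert c.area_nm2 == 400.0 and c.perimeter_nm == 20.0


class TestCircleReference:
    @pytest.mark.parametrize("d,per,area", [(1, np.pi, np.pi / 4), (10, 31.4159, 78.5398)])
    def test_closed_form(self, d, per, area):
        p, a = circle_reference(d)
        np.testing.assert_allclose([p, a], [per, area], rtol=1e-4)

    def test_rasterized_discs_converge_to_curve(self):
        """Relative error of digital discs against πd decreases with d."""
        errs = []
        for d in (9, 15, 21, 27, 31):
            n = d + 6
            ys, xs = np.mgrid[0:n, 0:n]
            m = (ys - n // 2) ** 2 + (xs - n // 2) ** 2 <= (d / 2.0) ** 2
            (c,) = measure_clusters(m)
            per_ref, area_ref = circle_reference(d)
            errs.append(abs(c.area_px - area_ref) / area_ref)
        assert errs[-1] < errs[0]


class TestMorphologyOnScenes:
    def test_rings_have_larger_perimeter_to_area_ratio_than_dots(self):
        """Ring staining is thresholded into more elongated clusters than dots."""
        from scipy.stats import mannwhitneyu

        from peroxiquant.coloc import extract_patch
        from peroxiquant.detection import find_maxima, make_regions
        from peroxiquant.scene import SceneSpec, generate_scene
        from peroxiquant._geometry import disc_mask

        ratios = {}
        for morph in ("ring", "dot"):
            vals = []
            for seed in range(3):
                spec = SceneSpec(
                    image_size_px=(448, 448),
                    n_organelles=18,
                    diameter_range_nm=(240.0, 340.0),
                    morphology_mix={morph: 1.0},
                    min_separation_nm=1100.0,
                    seed=100 + seed,
                )
                stack, _ = generate_scene(spec)
                maxima = find_maxima(stack.channels[0], 2.0, 10)
                regions = make_regions(maxima, stack.shape)
                for i, reg in enumerate(regions):
                    patch = extract_patch(stack.channels[1], reg)
                    for c in region_cluster_shapes(patch, region_id=i, disc=disc_mask(19)):
                        if c.area_px >= 4:
                            vals.append(c.perimeter_px / c.area_px)
            ratios[morph] = vals
        assert len(ratios["ring"]) >= 50 and len(ratios["dot"]) >= 50
        stat = mannwhitneyu(ratios["ring"], ratios["dot"], alternative="greater")
        assert np.median(ratios["ring"]) > np.median(ratios["dot"])
        assert stat.pvalue < 0.01
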