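import numpy as np
import pytest

from peroxiquant.detection import find_maxima, make_regions
from peroxiquant.intensity import (
    RegionIntensityPair,
    cell_correlation,
    compare_groups,
    gaussian_peak,
    integrate_regions,
    line_profile_fwhm,
    normalized_histogram,
)

from _oracles import enumerate_disc_pixels


def _pairs(gs, rs, kind="peroxisomal"):
    return [RegionIntensityPair(i, g, r, kind) for i, (g, r) in enumerate(zip(gs, rs))]


class TestIntegrateRegions:
    def test_sums_match_enumeration_oracle(self, congruent_scene):
        stack, _ = congruent_scene
        maxima = find_maxima(stack.channels[0], 2.0, 10)
        regions = make_regions(maxima, stack.shape)
        pairs = integrate_regions(stack, regions, 0, 1)
        for reg, pr in zip(regions, pairs):
            px = enumerate_disc_pixels(reg.center, reg.diameter_px)
            g = sum(float(stack.channels[0][r, c]) for r, c in px)
            r_ = sum(float(stack.channels[1][r, c]) for r, c in px)
            assert pr.g == g and pr.r == r_

    def test_delta_image_integrates_once(self):
        from peroxiquant.detection import MaximumPoint
        from peroxiquant.scene import ImageStack

        img = np.zeros((64, 64))
        img[30, 30] = 100.0
        stack = ImageStack(
            channels=[img, img.copy()], pixel_size_nm=20.0,
            meta=[{"label": "matrix", "modality": "confocal"},
                  {"label": "protein_a", "modality": "sted"}],
        )
        regions = make_regions(
            [MaximumPoint((30, 30), 1.0), MaximumPoint((50, 20), 1.0)], (64, 64)
        )
        pairs = integrate_regions(stack, regions, 0, 1)
        assert (pairs[0].g, pairs[0].r) == (100.0, 100.0)
        assert (pairs[1].g, pairs[1].r) == (0.0, 0.0)


class TestCellCorrelation:
    @pytest.mark.parametrize(
        "gs,rs,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_values(self, gs, rs, expected):
        out = cell_correlation(_pairs(gs, rs))
        np.testing.assert_allclose(out.pearson_r, expected, atol=1e-12)

    def test_degenerate_set_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            cell_correlation(_pairs([1, 1, 1], [2, 3, 4]))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        gs = rng.uniform(0, 100, 30)
        rs = rng.uniform(0, 100, 30)
        r1 = cell_correlation(_pairs(gs, rs)).pearson_r
        r2 = cell_correlation(_pairs(3.7 * gs + 11.0, rs)).pearson_r
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestNormalizedHistogram:
    def test_max_value_lands_in_top_bin(self):
        h = normalized_histogram([40.0], 40.0)
        assert h.counts[-1] == 1 and h.counts[:-1].sum() == 0

    def test_zeros_counted(self):
        h = normalized_histogram([0.0, 0.0, 0.0], 10.0)
        assert h.n_zero == 3 and h.counts[0] == 3

    def test_quartile_values_bin_individually(self):
        h = normalized_histogram([10, 20, 30, 40], 40.0)
        hot = np.nonzero(h.counts)[0]
        # 0.25, 0.5, 0.75 are bin edges; right-open binning puts them in the
        # bins starting at those edges, 1.0 in the closed top bin
        assert list(hot) == [6, 12, 18, 24]
        assert h.counts.sum() == 4

    def test_values_above_one_clipped_and_counted(self):
        h = normalized_histogram([50.0], 40.0, kind="random")
        assert h.n_clipped == 1 and h.counts[-1] == 1

    def test_mass_conserved_when_pooling(self):
        h1 = normalized_histogram([1, 2, 3], 4.0)
        h2 = normalized_histogram([2, 2], 4.0)
        pooled = h1.pooled_with(h2)
        assert pooled.counts.sum() == 5

    def test_nonpositive_reference_is_an_error(self):
        with pytest.raises(ValueError):
            normalized_histogram([1.0], 0.0)


class TestGaussianPeak:
    def test_recovers_simulated_truncated_normal_peak(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(0.5, 0.1, size=100_000)
        draws = draws[(draws >= 0) & (draws <= 1)]
        h = normalized_histogram(draws, 1.0)
        mu, sigma = gaussian_peak(h)
        assert abs(mu - 0.5) < 0.01
        assert abs(sigma - 0.1) < 0.01

    def test_too_few_bins_rejected(self):
        h = normalized_histogram([0.1] * 3 + [0.9] * 3, 1.0)
        with pytest.raises(ValueError, match="5 nonzero bins"):
            gaussian_peak(h)


class TestLineProfileFWHM:
    def test_gaussian_spot_closed_form(self):
        sigma_nm = 50.0
        ys, xs = np.mgrid[0:64, 0:64].astype(float)
        img = np.exp(-(((ys - 32) * 20) ** 2 + ((xs - 32) * 20) ** 2) / (2 * sigma_nm**2))
        fw = line_profile_fwhm(img, (32, 5), (32, 59), pixel_size_nm=20.0)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma_nm  # 117.7 nm
        assert abs(fw - expected) / expected < 0.05

    def test_rectangular_pulse_width(self):
        img = np.zeros((16, 64))
        img[:, 20:31] = 5.0  # 11-px-wide pulse
        fw = line_profile_fwhm(img, (8, 0), (8, 63), pixel_size_nm=1.0)
        assert abs(fw - 11.0) <= 1.0

    def test_monotone_profile_is_an_error(self):
        img = np.tile(np.arange(64.0), (16, 1))
        with pytest.raises(ValueError, match="no peak"):
            line_profile_fwhm(img, (8, 0), (8, 63))


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = list(np.linspace(0, 1, 10))
        f, p, table = compare_groups({"a": g, "b": g, "c": g})
        assert p > 0.99
        assert (table["reject"] == False).all()  # noqa: E712

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        f, p, table = compare_groups(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(5, 1, 20)}
        )
        assert p < 0.001
        assert table["reject"].all()

    def test_only_shifted_group_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        c = rng.normal(5, 1, 20)
        _, _, table = compare_groups({"a": a, "b": b, "c": c})
        for _, row in table.iterrows():
            involves_c = "c" in (row["group1"], row["group2"])
            assert bool(row["reject"]) == involves_c
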