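import numpy as np
import pytest

from peroxiquant.scene import (
    SceneSpec,
    apply_known_shift,
    generate_scene,
    read_scene,
    true_rim_distance_nm,
    write_scene,
)
from peroxiquant._geometry import fwhm_to_sigma

from conftest import ring_scene_spec


def small_spec(**kw):
    base = dict(
        image_size_px=(192, 192),
        n_organelles=4,
        diameter_range_nm=(160.0, 300.0),
        morphology_mix={"ring": 1.0},
        min_separation_nm=900.0,
        seed=5,
    )
    base.update(kw)
    return SceneSpec(**base)


class TestSceneSpecValidation:
    def test_rejects_inverted_diameter_range(self):
        with pytest.raises(ValueError, match="min < max"):
            small_spec(diameter_range_nm=(300.0, 160.0))

    def test_rejects_subpixel_organelles(self):
        with pytest.raises(ValueError, match="below 2 pixels"):
            small_spec(diameter_range_nm=(30.0, 300.0))

    def test_rejects_unnormalized_morphology_mix(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_spec(morphology_mix={"ring": 0.5, "dot": 0.2})

    def test_rejects_negative_background(self):
        with pytest.raises(ValueError):
            small_spec(background_rate=-1.0)


class TestGenerateScene:
    def test_seed_determinism_bit_identical(self):
        spec = small_spec()
        s1, _ = generate_scene(spec)
        s2, _ = generate_scene(spec)
        for c1, c2 in zip(s1.channels, s2.channels):
            np.testing.assert_array_equal(c1, c2)

    def test_empty_scene_is_background_only(self):
        spec = small_spec(n_organelles=0, background_rate=0.0)
        stack, gt = generate_scene(spec)
        assert gt.n_organelles == 0
        for c in stack.channels:
            assert c.sum() == 0

    def test_matrix_confined_to_interiors(self):
        """Noiseless matrix flux concentrates inside the organelle discs."""
        spec = small_spec(background_rate=0.0)
        _, gt = generate_scene(spec)
        mean = gt.mean_channels["matrix"]
        h, w = mean.shape
        ys, xs = np.mgrid[0:h, 0:w]
        inside = np.zeros((h, w), dtype=bool)
        for (r0, c0), d in zip(gt.centers_px, gt.diameters_nm):
            rad = d / 2.0 / spec.pixel_size_nm + 3 * fwhm_to_sigma(250.0) / 20.0
            inside |= (ys - r0) ** 2 + (xs - c0) ** 2 <= rad**2
        assert mean[inside].sum() / mean.sum() > 0.99

    def test_zero_offset_channels_identical(self):
        """Congruent domains: protein channels agree up to amplitude scale."""
        spec = small_spec(
            domain_offset_deg=0.0,
            photon_budget={"matrix": np.inf, "protein_a": np.inf, "protein_b": np.inf},
            background_rate=0.0,
        )
        stack, _ = generate_scene(spec)
        a = stack.channels[1]
        b = stack.channels[2]
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_noiseless_total_flux_is_budget_times_n(self):
        spec = small_spec(background_rate=0.0)
        _, gt = generate_scene(spec)
        for name, budget in spec.photon_budget.items():
            if name == "filament":
                continue
            total = gt.mean_channels[name].sum()
            np.testing.assert_allclose(total, budget * spec.n_organelles, rtol=1e-9)

    def test_dot_spot_profile_matches_disc_convolution_oracle(self):
        """A dot organelle renders as disc ⊗ Gaussian: FWHM agrees within 1 px
        with a direct numerical convolution of the disc indicator."""
        from scipy.ndimage import gaussian_filter
        from peroxiquant.intensity import line_profile_fwhm

        d_nm, psf = 300.0, 60.0
        spec = small_spec(
            n_organelles=1,
            diameter_range_nm=(d_nm - 1e-6, d_nm + 1e-6),
            morphology_mix={"dot": 1.0},
            psf_fwhm_nm={"matrix": 250.0, "protein_a": psf, "protein_b": psf},
            photon_budget={"matrix": np.inf, "protein_a": np.inf, "protein_b": np.inf},
            background_rate=0.0,
            min_separation_nm=0.0,
        )
        stack, gt = generate_scene(spec)
        r0, c0 = gt.centers_px[0]
        fw_render = line_profile_fwhm(
            stack.channels[1], (r0, c0 - 20), (r0, c0 + 20), spec.pixel_size_nm
        )

        # oracle: numerically convolve the exact disc indicator with the PSF
        ys, xs = np.mgrid[0:81, 0:81].astype(float)
        disc = ((ys - 40) ** 2 + (xs - 40) ** 2 <= (d_nm / 2 / 20.0) ** 2).astype(float)
        blurred = gaussian_filter(disc, fwhm_to_sigma(psf) / 20.0, mode="constant")
        fw_oracle = line_profile_fwhm(blurred, (40, 20), (40, 60), spec.pixel_size_nm)
        assert abs(fw_render - fw_oracle) <= 1.0 * spec.pixel_size_nm

    def test_rim_distance_increases_with_offset(self):
        d = 400.0
        dists = [true_rim_distance_nm(d, off) for off in (0, 45, 90, 135, 180)]
        assert all(b > a for a, b in zip(dists, dists[1:]))
        np.testing.assert_allclose(
            true_rim_distance_nm(d, 90.0), (d / 2) * np.pi / 2
        )

    def test_filament_channel_rendered_independently(self):
        spec = small_spec(filament_channel=True)
        stack, _ = generate_scene(spec)
        assert len(stack.channels) == 4
        assert stack.meta[3]["label"] == "filament"
        assert stack.channels[3].sum() > 0


class TestApplyKnownShift:
    def test_zero_shift_is_identity(self, congruent_scene):
        stack, _ = congruent_scene
        out = apply_known_shift(stack, (0, 0), channel=1)
        np.testing.assert_array_equal(out.channels[1], stack.channels[1])

    def test_shift_then_inverse_restores_common_support(self, congruent_scene):
        stack, _ = congruent_scene
        fwd = apply_known_shift(stack, (3, -2), channel=1)
        back = apply_known_shift(fwd, (-3, 2), channel=1)
        a = stack.channels[1]
        b = back.channels[1]
        # common support: rows ..-3, cols 2.. survive the round trip
        np.testing.assert_array_equal(a[:-3, 2:], b[:-3, 2:])

    def test_delta_relocates_exactly(self):
        from peroxiquant.scene import ImageStack

        img = np.zeros((32, 32))
        img[10, 12] = 7.0
        stack = ImageStack(
            channels=[img], pixel_size_nm=20.0,
            meta=[{"label": "matrix", "modality": "confocal"}],
        )
        out = apply_known_shift(stack, (5, 5), channel=0)
        assert out.channels[0][15, 17] == 7.0
        assert out.channels[0].sum() == 7.0

    def test_rejects_shift_outside_window(self, congruent_scene):
        stack, _ = congruent_scene
        with pytest.raises(ValueError, match="window"):
            apply_known_shift(stack, (19, 0), channel=1)


def test_scene_tiff_roundtrip(tmp_path):
    spec = small_spec()
    stack, gt = generate_scene(spec)
    write_scene(stack, gt, tmp_path)
    loaded, gt2 = read_scene(tmp_path)
    assert len(loaded.channels) == len(stack.channels)
    np.testing.assert_allclose(loaded.channels[0], stack.channels[0])
    np.testing.assert_allclose(gt2.centers_px, gt.centers_px)
    assert gt2.morphology == gt.morphology
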