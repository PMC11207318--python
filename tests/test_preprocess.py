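"""Geometry, ELM calibration, wavelet denoising and derivative checks."""

import numpy as np
import pytest

from hyperyield.datacube import SensorGeometry, SpectralCube
from hyperyield.preprocess import (
    apply_elm,
    compute_gsd,
    denoise_wavelet,
    fit_elm,
    invert_elm,
    panel_mean_spectrum,
    spectral_derivative,
    swath_path_difference,
)

WL = np.linspace(400.0, 1000.0, 272)


class TestGeometry:
    def test_gsd_collapses_to_pitch_when_alt_equals_focal(self):
        g = SensorGeometry(altitude=0.02, pixel_pitch=1e-5, focal_length=0.02, swath_width=1.0)
        assert compute_gsd(g) == pytest.approx(1e-5)

    def test_gsd_arithmetic(self):
        g = SensorGeometry(altitude=100.0, pixel_pitch=1e-5, focal_length=0.02, swath_width=15.0)
        assert compute_gsd(g) == pytest.approx(0.05)

    def test_nominal_campaign_gsd(self):
        # any pitch/focal combination with p/f = 6.3e-4 at 100 m altitude
        g = SensorGeometry(altitude=100.0, pixel_pitch=6.3e-6, focal_length=0.01, swath_width=15.0)
        assert compute_gsd(g) == pytest.approx(0.063)

    def test_geometry_positivity(self):
        with pytest.raises(ValueError):
            SensorGeometry(altitude=-1.0, pixel_pitch=1e-5, focal_length=0.02, swath_width=15.0)

    def test_swath_zero_width(self):
        assert swath_path_difference(100.0, 0.0) == (0.0, 0.0)

    def test_swath_closed_form(self):
        excess, pct = swath_path_difference(100.0, 15.0)
        assert excess == pytest.approx(np.hypot(100.0, 7.5) - 100.0)
        assert excess == pytest.approx(0.2809, abs=1e-4)
        assert pct == pytest.approx(0.2809, abs=1e-4)
        assert pct < 0.3  # the equidistance assumption holds


class TestELM:
    def test_two_point_line_solve(self):
        c = fit_elm(np.array([2.0]), np.array([9.0]), np.array([550.0]), 0.06, 0.55)
        assert c.gain[0] == pytest.approx(0.07)
        assert c.bias[0] == pytest.approx(-0.08)

    def test_identity_calibration(self):
        c = fit_elm(np.array([0.06, 0.06]), np.array([0.55, 0.55]), np.array([500.0, 600.0]))
        np.testing.assert_allclose(c.gain, 1.0)
        np.testing.assert_allclose(c.bias, 0.0, atol=1e-15)

    def test_degenerate_band_named(self):
        with pytest.raises(ValueError, match=r"band\(s\) \[1\]"):
            fit_elm(np.array([2.0, 3.0]), np.array([9.0, 3.0]), np.array([500.0, 600.0]))

    def test_apply_arithmetic(self):
        cube = SpectralCube(np.full((1, 1, 1), 5.0), [550.0], "radiance", 1.0)
        c = fit_elm(np.array([2.0]), np.array([9.0]), np.array([550.0]))
        out = apply_elm(cube, c)
        assert out.values[0, 0, 0] == pytest.approx(0.27)
        assert out.domain == "reflectance"

    def test_apply_is_affine(self, random_cube):
        c1, c2 = random_cube(seed=1), random_cube(seed=2)
        coeffs = fit_elm(
            np.full(5, 1.0), np.full(5, 4.0), c1.wavelengths
        )
        a = 0.3
        mix = SpectralCube(
            a * c1.values + (1 - a) * c2.values, c1.wavelengths, "radiance", c1.gsd
        )
        lhs = apply_elm(mix, coeffs).values
        rhs = a * apply_elm(c1, coeffs).values + (1 - a) * apply_elm(c2, coeffs).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_panel_round_trip_and_inversion(self, small_scene):
        cube = small_scene.cube
        dark = panel_mean_spectrum(cube, small_scene.panel_masks["dark"])
        light = panel_mean_spectrum(cube, small_scene.panel_masks["light"])
        coeffs = fit_elm(dark, light, cube.wavelengths)
        np.testing.assert_allclose(coeffs.gain * dark + coeffs.bias, 0.06, atol=1e-12)
        np.testing.assert_allclose(coeffs.gain * light + coeffs.bias, 0.55, atol=1e-12)
        refl = apply_elm(cube, coeffs)
        back = invert_elm(refl, coeffs)
        np.testing.assert_allclose(back.values, cube.values, rtol=1e-5, atol=1e-6)

    def test_wavelength_mismatch_rejected(self, random_cube):
        cube = random_cube()
        coeffs = fit_elm(np.full(5, 1.0), np.full(5, 4.0), cube.wavelengths + 5.0)
        with pytest.raises(ValueError, match="grids"):
            apply_elm(cube, coeffs)

    def test_coeffs_csv_round_trip(self, tmp_path):
        c = fit_elm(np.array([2.0, 1.0]), np.array([9.0, 5.0]), np.array([500.0, 600.0]))
        c.to_csv(tmp_path / "elm.csv")
        from hyperyield.preprocess import ELMCoefficients

        back = ELMCoefficients.from_csv(tmp_path / "elm.csv")
        np.testing.assert_allclose(back.gain, c.gain)
        np.testing.assert_allclose(back.bias, c.bias)


def _spectrum_cube(spectrum, reps=(1, 2, 2)):
    return SpectralCube(np.tile(spectrum[:, None, None], reps), WL, "radiance", 1.0)


class TestDenoising:
    def test_constant_spectrum_unchanged(self):
        cube = _spectrum_cube(np.full(len(WL), 3.0))
        out = denoise_wavelet(cube)
        np.testing.assert_allclose(out.values, 3.0, atol=1e-10)

    def test_noise_mse_strictly_reduced(self):
        rng = np.random.default_rng(3)
        clean = 0.05 + 0.45 / (1 + np.exp(-(WL - 715) / 14))
        noisy = clean + rng.normal(0, 0.01, len(WL))
        out = denoise_wavelet(_spectrum_cube(noisy)).values[:, 0, 0]
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_narrow_absorption_dip_mitigated_not_removed(self):
        """A narrow 762 nm dip is damped by smoothing yet still present."""
        rng = np.random.default_rng(3)
        base = 0.05 + 0.45 / (1 + np.exp(-(WL - 715) / 14))
        dip = 0.04 * np.exp(-0.5 * ((WL - 762) / 3.0) ** 2)
        noisy = base - dip + rng.normal(0, 0.01, len(WL))
        out = denoise_wavelet(_spectrum_cube(noisy)).values[:, 0, 0]
        i762 = np.argmin(np.abs(WL - 762))
        depth_after = base[i762] - out[i762]
        assert 0.0 < depth_after < 0.04

    def test_idempotent_on_smooth_spectra(self):
        smooth = 0.05 + 0.45 / (1 + np.exp(-(WL - 715) / 14))
        once = denoise_wavelet(_spectrum_cube(smooth))
        np.testing.assert_allclose(once.values[:, 0, 0], smooth, atol=1e-8)
        twice = denoise_wavelet(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)

    def test_shape_and_wavelengths_preserved(self, small_scene):
        out = denoise_wavelet(small_scene.cube)
        assert out.shape == small_scene.cube.shape
        np.testing.assert_array_equal(out.wavelengths, small_scene.cube.wavelengths)

    def test_short_spectrum_rejected(self):
        cube = SpectralCube(np.ones((3, 1, 1)), [500.0, 600.0, 700.0], "radiance", 1.0)
        with pytest.raises(ValueError, match="filter support"):
            denoise_wavelet(cube)


class TestDerivative:
    def test_constant_gives_zero(self):
        out = spectral_derivative(_spectrum_cube(np.full(len(WL), 2.0)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        assert out.domain == "derivative"

    def test_linear_ramp_exact(self):
        a, b = 3e-4, -0.1
        out = spectral_derivative(_spectrum_cube(a * WL + b))
        np.testing.assert_allclose(out.values, a, rtol=1e-10)

    def test_logistic_maximum_at_inflection(self):
        spec = 1.0 / (1 + np.exp(-(WL - 715) / 14))
        out = spectral_derivative(_spectrum_cube(spec)).values[:, 0, 0]
        assert abs(WL[np.argmax(out)] - 715.0) <= WL[1] - WL[0]

    def test_single_band_rejected(self):
        cube = SpectralCube(np.ones((1, 1, 1)), [500.0], "radiance", 1.0)
        with pytest.raises(ValueError, match="2 bands"):
            spectral_derivative(cube)
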