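"""Band-equivalent reflectance convolution against brute-force quadrature."""

import numpy as np
import pytest

from uavcal.sensor import (
    Band,
    BandSet,
    CameraProfile,
    CoverageError,
    DegenerateResponseError,
    HyperspectralSpectrum,
    band_equivalent_reflectance,
    convolve_all_bands,
    gaussian_response,
)


def fine_grid_oracle(spectrum, band, step=0.01):
    """Brute-force quadrature of the response-weighted mean on a dense grid.

    Independent of the implementation: interpolates both curves onto a
    0.01 nm grid and integrates with the composite trapezoid rule.
    """
    s, e = band.support
    grid = np.arange(s, e + step / 2, step)
    r = np.interp(grid, spectrum.wavelengths, spectrum.values)
    w = np.interp(grid, band.response[:, 0], band.response[:, 1])
    return np.trapezoid(r * w, grid) / np.trapezoid(w, grid)


def vegetation_like_spectrum():
    """Smooth leaf-like curve: low visible, red-edge ramp, NIR plateau."""
    wl = np.arange(400.0, 1100.0, 1.0)
    refl = (0.05
            + 0.05 * np.exp(-0.5 * ((wl - 550) / 40.0) ** 2)
            + 0.45 / (1.0 + np.exp(-(wl - 720) / 18.0)))
    return HyperspectralSpectrum.from_arrays(wl, refl)


class TestBandEquivalentReflectance:
    def test_flat_spectrum_returns_constant(self):
        spectrum = HyperspectralSpectrum.constant(0.5)
        band = Band(1, 670.0, gaussian_response(670.0))
        assert band_equivalent_reflectance(spectrum, band) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_constant_exact_for_random_response_shapes(self):
        rng = np.random.default_rng(42)
        spectrum = HyperspectralSpectrum.constant(0.37)
        for _ in range(100):
            center = rng.uniform(450, 1000)
            half = rng.uniform(3, 30)
            wl = np.sort(rng.uniform(center - half, center + half, 15))
            wl = np.unique(wl)
            if len(wl) < 2:
                continue
            weights = rng.uniform(0.0, 1.0, len(wl))
            weights[weights.argmax()] += 0.5  # guard against all-tiny weights
            band = Band(1, center, np.column_stack([wl, weights]))
            val = band_equivalent_reflectance(spectrum, band)
            assert val == pytest.approx(0.37, abs=1e-12)

    def test_narrow_response_picks_local_value(self):
        # response concentrated on a 1-nm bin at 800 nm; spectrum linear
        # 0.2 -> 0.4 over 700-900 nm, so the value at 800 nm is 0.3
        spectrum = HyperspectralSpectrum.from_arrays([700, 900], [0.2, 0.4])
        band = Band(1, 800.0, np.array([[799.5, 1.0], [800.5, 1.0]]))
        assert band_equivalent_reflectance(spectrum, band) == pytest.approx(
            0.3, abs=1e-9
        )

    def test_triangular_response_matches_fine_grid_oracle(self):
        response = np.array([[660.0, 0.0], [670.0, 1.0], [680.0, 0.0]])
        band = Band(1, 670.0, response)
        wl = np.arange(600.0, 760.0, 1.0)
        spectrum = HyperspectralSpectrum.from_arrays(wl, 0.001 * (wl - 600.0))
        value = band_equivalent_reflectance(spectrum, band)
        assert value == pytest.approx(fine_grid_oracle(spectrum, band), abs=1e-6)

    def test_linearity(self):
        band = Band(1, 700.0, gaussian_response(700.0))
        wl = np.arange(600.0, 800.0, 2.0)
        r1 = 0.1 + 0.002 * (wl - 600)
        r2 = 0.4 - 0.001 * (wl - 600)
        a, b = 0.3, 0.6
        combo = HyperspectralSpectrum.from_arrays(wl, a * r1 + b * r2)
        v1 = band_equivalent_reflectance(
            HyperspectralSpectrum.from_arrays(wl, r1), band)
        v2 = band_equivalent_reflectance(
            HyperspectralSpectrum.from_arrays(wl, r2), band)
        assert band_equivalent_reflectance(combo, band) == pytest.approx(
            a * v1 + b * v2, abs=1e-10
        )

    def test_value_bounded_by_spectrum_over_support(self):
        rng = np.random.default_rng(7)
        band = Band(1, 850.0, gaussian_response(850.0))
        s, e = band.support
        for _ in range(20):
            wl = np.arange(400.0, 1100.0, 5.0)
            refl = rng.uniform(0.0, 1.0, len(wl))
            spectrum = HyperspectralSpectrum.from_arrays(wl, refl)
            val = band_equivalent_reflectance(spectrum, band)
            inside = (wl >= s - 5) & (wl <= e + 5)
            assert refl[inside].min() - 1e-9 <= val <= refl[inside].max() + 1e-9

    def test_coverage_error(self):
        spectrum = HyperspectralSpectrum.from_arrays([500, 600], [0.1, 0.2])
        band = Band(1, 800.0, gaussian_response(800.0))
        with pytest.raises(CoverageError):
            band_equivalent_reflectance(spectrum, band)

    def test_degenerate_response_error(self):
        spectrum = HyperspectralSpectrum.constant(0.5)
        band = Band(1, 700.0, np.array([[695.0, 0.0], [705.0, 0.0]]))
        with pytest.raises(DegenerateResponseError):
            band_equivalent_reflectance(spectrum, band)


class TestConvolveAllBands:
    def test_flat_spectrum(self, camera):
        out = convolve_all_bands(HyperspectralSpectrum.constant(0.3), camera)
        np.testing.assert_allclose(out, 0.3, atol=1e-12)
        assert out.shape == (12,)

    def test_step_spectrum_separates_visible_and_nir(self, camera):
        wl = np.arange(400.0, 1100.0, 0.25)
        refl = np.where(wl < 745.0, 0.05, 0.5)
        out = convolve_all_bands(
            HyperspectralSpectrum.from_arrays(wl, refl), camera
        )
        np.testing.assert_allclose(out[:8], 0.05, atol=1e-6)  # 490-720 nm
        np.testing.assert_allclose(out[8:], 0.5, atol=1e-6)   # 800-950 nm

    def test_vegetation_spectrum_matches_oracle(self, camera):
        spectrum = vegetation_like_spectrum()
        out = convolve_all_bands(spectrum, camera)
        expected = [fine_grid_oracle(spectrum, b) for b in camera.band_set]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_missing_responses_reported_per_band(self):
        cam = CameraProfile.reference(with_responses=False)
        with pytest.raises(ValueError, match=r"\[1,"):
            convolve_all_bands(HyperspectralSpectrum.constant(0.3), cam)


class TestDomainTypes:
    def test_reference_band_centers(self, camera):
        np.testing.assert_array_equal(
            camera.band_set.centers,
            [490, 520, 550, 570, 670, 680, 700, 720, 800, 850, 900, 950],
        )
        assert (camera.image_width, camera.image_height) == (1280, 1024)
        assert (camera.fov_h, camera.fov_v) == (38.26, 30.97)

    def test_band_set_rejects_unsorted_centers(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BandSet((Band(1, 550.0), Band(2, 490.0)))

    def test_spectrum_rejects_out_of_range_reflectance(self):
        with pytest.raises(ValueError):
            HyperspectralSpectrum.from_arrays([400, 500], [0.2, 1.8])

    def test_response_rejects_negative_weights(self):
        with pytest.raises(ValueError, match="non-negative"):
            Band(1, 700.0, np.array([[690.0, 1.0], [710.0, -0.1]]))
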