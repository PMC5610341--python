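"""Spectrometer chain: mosaic summation, calibration, peaks, reflectance ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemospec as hs
from hemospec.processing import DispersionMap, save_dispersion, load_dispersion
from hemospec.spectrum import Spectrum


class TestBayerToGrey:
    def test_uniform_block_sum(self):
        out = hs.bayer_to_grey(np.full((4, 4), 10))
        np.testing.assert_array_equal(out, np.full((2, 2), 40))

    def test_single_pixel_lands_in_one_cell(self):
        raw = np.zeros((6, 6), dtype=int)
        raw[3, 4] = 7
        out = hs.bayer_to_grey(raw)
        assert out.sum() == 7
        assert (out == 7).sum() == 1
        assert out[1, 2] == 7

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_counts_conserved(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.integers(0, 1024, size=(8, 8))
        assert hs.bayer_to_grey(raw).sum() == raw.sum()

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError, match="even"):
            hs.bayer_to_grey(np.zeros((5, 4)))

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            hs.bayer_to_grey(np.zeros((4, 4)), pattern="XYZW")


class TestImageToSpectrum:
    def test_all_ones_sums_to_row_count(self):
        spec = hs.image_to_spectrum(np.ones((7, 5)))
        np.testing.assert_array_equal(spec.values, np.full(5, 7.0))

    def test_single_column_gives_delta(self):
        img = np.zeros((4, 9))
        img[:, 3] = 2.0
        spec = hs.image_to_spectrum(img)
        assert spec.values[3] == 8.0
        assert spec.values.sum() == 8.0

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        img = rng.random((6, 11))
        a = hs.image_to_spectrum(img, slit_axis="rows")
        b = hs.image_to_spectrum(img.T, slit_axis="cols")
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            hs.image_to_spectrum(np.zeros((0, 4)))

    def test_chain_conserves_counts(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(0, 1023, size=(16, 32))
        spec = hs.image_to_spectrum(hs.bayer_to_grey(raw))
        assert spec.values.sum() == raw.sum()


class TestWavelengthCalibration:
    def test_exact_collinear_points(self):
        fit = hs.calibrate_wavelength([100, 200, 300], [500, 550, 600])
        assert fit.dispersion.slope == pytest.approx(0.5)
        assert fit.dispersion.intercept == pytest.approx(450.0)
        assert fit.rms_nm == pytest.approx(0.0, abs=1e-9)

    def test_identity_pairs(self):
        fit = hs.calibrate_wavelength([1, 2, 3, 4], [1, 2, 3, 4])
        assert fit.dispersion.slope == pytest.approx(1.0)
        assert fit.dispersion.intercept == pytest.approx(0.0, abs=1e-12)

    def test_jittered_line_recovered_within_standard_errors(self):
        # closed-form least-squares oracle: slope SE = sigma / sqrt(Sxx)
        rng = np.random.default_rng(7)
        px = np.linspace(0, 950, 20)
        true_slope, true_icpt, sigma = 0.62, 410.0, 0.1
        nm = true_slope * px + true_icpt + sigma * rng.standard_normal(20)
        fit = hs.calibrate_wavelength(px, nm)
        se_slope = sigma / np.sqrt(np.sum((px - px.mean()) ** 2))
        assert abs(fit.dispersion.slope - true_slope) < 3 * se_slope

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            hs.calibrate_wavelength([100], [500])
        with pytest.raises(ValueError):
            hs.calibrate_wavelength([100, 100, 100], [500, 550, 600])

    def test_json_round_trip(self, tmp_path):
        fit = hs.calibrate_wavelength([100, 200, 300], [500, 550, 600])
        path = tmp_path / "cal.json"
        save_dispersion(path, fit)
        disp = load_dispersion(path)
        assert disp == fit.dispersion


class TestPeaksAndFwhm:
    def test_gaussian_sigma_gives_5nm_fwhm(self):
        # FWHM = 2 sqrt(2 ln 2) sigma = 5.00 nm for sigma = 2.123 nm
        grid = np.arange(480.0, 560.0, 1.0)
        v = np.exp(-0.5 * ((grid - 520.3) / 2.123) ** 2)
        report = hs.find_peaks_fwhm(Spectrum(grid, v))
        assert len(report) == 1
        assert report.fwhm_nm[0] == pytest.approx(5.00, abs=0.05)
        assert report.centers_nm[0] == pytest.approx(520.3, abs=0.3)

    def test_triangle_fwhm_equals_half_width_at_half_height(self):
        grid = np.linspace(500, 540, 161)
        w = 12.0  # full width at half height of a symmetric triangle
        v = np.clip(1.0 - np.abs(grid - 520.0) / w, 0.0, None)
        report = hs.find_peaks_fwhm(Spectrum(grid, v))
        assert report.fwhm_nm[0] == pytest.approx(w, abs=1e-6)

    def test_two_separated_gaussians_both_reported(self):
        grid = np.linspace(450, 620, 341)
        v = (np.exp(-0.5 * ((grid - 500) / 2.2) ** 2)
             + np.exp(-0.5 * ((grid - 550) / 2.2) ** 2))
        report = hs.find_peaks_fwhm(Spectrum(grid, v))
        assert len(report) == 2

    def test_flat_spectrum_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            hs.find_peaks_fwhm(Spectrum(np.arange(10.0), np.ones(10)))


class TestDiffuseReflectance:
    grid = np.linspace(430, 630, 21)

    def _spec(self, vals):
        return Spectrum(self.grid, np.asarray(vals, dtype=float) * np.ones(21))

    @pytest.mark.parametrize(
        "sample_level,expected", [(100.0, 0.0), (600.0, 1.0), (350.0, 0.5)]
    )
    def test_constant_ratios(self, sample_level, expected):
        # background 100, reference 600: sample at bg -> 0, at ref -> 1, midway -> 0.5
        r = hs.diffuse_reflectance(
            self._spec(sample_level), self._spec(600.0), self._spec(100.0)
        )
        np.testing.assert_allclose(r.values, expected, atol=1e-14)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_joint_positive_rescaling(self, factor):
        rng = np.random.default_rng(3)
        bg = 50.0
        s = bg + rng.random(21) * 100
        ref = bg + 100 + rng.random(21) * 100
        base = hs.diffuse_reflectance(
            Spectrum(self.grid, s), Spectrum(self.grid, ref),
            self._spec(bg),
        )
        scaled = hs.diffuse_reflectance(
            Spectrum(self.grid, bg + (s - bg) * factor),
            Spectrum(self.grid, bg + (ref - bg) * factor),
            self._spec(bg),
        )
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)

    def test_nonpositive_denominator_masked_not_clipped(self):
        ref = np.full(21, 200.0)
        ref[5] = 50.0  # below background -> masked out
        r = hs.diffuse_reflectance(
            self._spec(150.0), Spectrum(self.grid, ref), self._spec(100.0)
        )
        assert len(r) == 20
        assert self.grid[5] not in r.wavelengths

    def test_grid_mismatch_rejected(self):
        other = Spectrum(self.grid[:-1], np.ones(20))
        with pytest.raises(ValueError, match="grid"):
            hs.diffuse_reflectance(self._spec(1.0), other, self._spec(0.0))


class TestFullChain:
    def test_line_centers_recovered_within_0p2_nm(self, tmp_path):
        disp = DispersionMap(slope=0.6, intercept=380.0)
        centers = [450.0, 550.0, 650.0]
        img = hs.synth_bayer_image(
            [(c, 5.0, 400.0) for c in centers], disp, shape=(16, 1024)
        )
        # through the PGM file format, as the instrument stores frames
        path = tmp_path / "frame.pgm"
        hs.write_pgm(path, img)
        raw = hs.read_pgm(path)
        np.testing.assert_array_equal(raw, img)

        spec = hs.image_to_spectrum(hs.bayer_to_grey(raw))
        px = hs.peak_pixel_positions(spec)
        assert len(px) == 3
        fit = hs.calibrate_wavelength(px, centers)
        recovered = fit.dispersion.pixel_to_nm(px)
        assert np.max(np.abs(recovered - centers)) < 0.2
        # grey-pixel dispersion is twice the raw-pixel dispersion
        assert fit.dispersion.slope == pytest.approx(1.2, abs=0.01)
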