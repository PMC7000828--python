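import numpy as np
import pytest

from ugimem.specio import (
    CalibrationError,
    DegenerateBackgroundError,
    BackgroundEstimate,
    MassSpectrum,
    SpectralMatrix,
    calibrate_offset,
    default_grid,
    estimate_background,
    peak_intensity,
    read_csv,
    read_hdf5,
    read_mzml,
    read_spectra,
    resample_to_grid,
    snr_transform,
    write_csv,
    write_hdf5,
    write_mzml,
)


def _gaussian_spectrum(center=500.0, fwhm=0.004, amplitude=100.0,
                       grid=None, baseline=0.0):
    if grid is None:
        grid = default_grid(499.0, 501.0, 0.001)
    sigma = fwhm / 2.3548
    intensity = baseline + amplitude * np.exp(
        -0.5 * ((grid - center) / sigma) ** 2
    )
    return MassSpectrum(grid, intensity, spot_id="s0")


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        spec = _gaussian_spectrum()
        path = tmp_path / "spec.csv"
        write_csv(spec, path)
        back = read_csv(path)
        np.testing.assert_allclose(back.mz, spec.mz, atol=1e-9)
        np.testing.assert_allclose(back.intensity, spec.intensity, atol=1e-9)

    def test_mzml_round_trip_via_pyteomics(self, tmp_path):
        spectra = [_gaussian_spectrum(500.0), _gaussian_spectrum(500.5)]
        spectra[1].spot_id = "s1"
        path = tmp_path / "plate.mzml"
        write_mzml(spectra, path)
        back = read_mzml(path)
        assert len(back) == 2
        for orig, re in zip(spectra, back):
            np.testing.assert_allclose(re.mz, orig.mz, atol=1e-9)
            np.testing.assert_allclose(re.intensity, orig.intensity, atol=1e-9)

    def test_hdf5_matrix_round_trip(self, tmp_path):
        grid = default_grid(400, 401, 0.01)
        matrix = SpectralMatrix(
            grid=grid,
            data=np.random.default_rng(0).random((3, grid.size)),
            spot_ids=["a", "b", "c"],
            offsets_ppm=np.array([1.0, -2.0, 0.5]),
        )
        path = tmp_path / "plate.h5"
        write_hdf5(matrix, path)
        back = read_hdf5(path)
        np.testing.assert_allclose(back.grid, matrix.grid)
        np.testing.assert_allclose(back.data, matrix.data)
        assert back.spot_ids == ["a", "b", "c"]
        np.testing.assert_allclose(back.offsets_ppm, matrix.offsets_ppm)

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "spec.xyz"
        path.write_text("")
        with pytest.raises(ValueError, match="format"):
            read_spectra(path)

    def test_non_ascending_mz_is_sorted_with_warning(self):
        with pytest.warns(UserWarning, match="ascending"):
            spec = MassSpectrum(np.array([2.0, 1.0, 3.0]),
                                np.array([20.0, 10.0, 30.0]))
        assert spec.mz.tolist() == [1.0, 2.0, 3.0]
        assert spec.intensity.tolist() == [10.0, 20.0, 30.0]


class TestBackground:
    def test_pure_gaussian_noise(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10.0, 2.0, 20_000)
        bg = estimate_background(values)
        assert bg.mu == pytest.approx(10.0, rel=0.05)
        assert bg.sigma == pytest.approx(2.0, rel=0.05)

    def test_constant_spectrum_is_degenerate(self):
        with pytest.raises(DegenerateBackgroundError):
            estimate_background(np.full(500, 7.0))

    def test_clipping_removes_a_huge_peak(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(10.0, 2.0, 20_000)
        spiked = noise.copy()
        spiked[100:110] += 1e5
        clean = estimate_background(noise)
        robust = estimate_background(spiked)
        assert robust.mu == pytest.approx(clean.mu, rel=0.05)
        assert robust.sigma == pytest.approx(clean.sigma, rel=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="100"):
            estimate_background(np.ones(50))


class TestSNR:
    def test_shift_and_scale_arithmetic(self):
        spec = MassSpectrum(np.array([1.0]), np.array([72.0]))
        out = snr_transform(spec, BackgroundEstimate(mu=10.0, sigma=2.0))
        assert out.intensity[0] == pytest.approx(31.0)

    def test_background_level_maps_to_zero(self):
        spec = MassSpectrum(np.array([1.0]), np.array([10.0]))
        out = snr_transform(spec, BackgroundEstimate(mu=10.0, sigma=2.0))
        assert out.intensity[0] == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        mz = default_grid(400, 402, 0.01)
        raw = rng.normal(10, 2, mz.size) + 50 * np.exp(
            -0.5 * ((mz - 401) / 0.002) ** 2
        )
        a, b = 3.7, 11.0
        spec1 = MassSpectrum(mz, raw)
        spec2 = MassSpectrum(mz, a * raw + b)
        bg1 = estimate_background(spec1)
        bg2 = BackgroundEstimate(mu=a * bg1.mu + b, sigma=a * bg1.sigma)
        out1 = snr_transform(spec1, bg1)
        out2 = snr_transform(spec2, bg2)
        np.testing.assert_allclose(out2.intensity, out1.intensity, rtol=1e-12)

    def test_zero_sigma_rejected(self):
        spec = MassSpectrum(np.array([1.0]), np.array([5.0]))
        with pytest.raises(ValueError):
            snr_transform(spec, BackgroundEstimate(mu=0.0, sigma=0.0))


class TestCalibration:
    def _offset_spectrum(self, offset_ppm, ref_mz=500.0):
        grid = default_grid(499.0, 501.0, 0.001)
        rng = np.random.default_rng(3)
        baseline = np.clip(rng.normal(10, 2, grid.size), 0, None)
        spec = MassSpectrum(grid, baseline)
        center = ref_mz * (1 + offset_ppm * 1e-6)
        spec.intensity += 500 * np.exp(
            -0.5 * ((grid - center) / 0.0017) ** 2
        )
        return spec

    def test_known_injected_offset_is_removed(self):
        spec = self._offset_spectrum(+5.0)
        fixed, offset = calibrate_offset(spec, 500.0)
        assert offset == pytest.approx(5.0, abs=1.0)
        apex = fixed.mz[np.argmax(fixed.intensity)]
        assert abs(apex - 500.0) <= 0.0015  # within one grid step

    def test_zero_offset_correction_is_tiny(self):
        spec = self._offset_spectrum(0.0)
        _, offset = calibrate_offset(spec, 500.0)
        assert abs(offset) < 2.0  # grid resolution scale (0.001/500 = 2 ppm)

    def test_missing_calibrant_raises(self):
        grid = default_grid(499.0, 501.0, 0.001)
        rng = np.random.default_rng(4)
        spec = MassSpectrum(grid, np.clip(rng.normal(10, 2, grid.size), 0, None))
        with pytest.raises(CalibrationError):
            calibrate_offset(spec, 500.0)

    def test_calibration_is_idempotent(self):
        spec = self._offset_spectrum(+8.0)
        once, off1 = calibrate_offset(spec, 500.0)
        twice, off2 = calibrate_offset(once, 500.0)
        assert abs(off2) < 2.0
        np.testing.assert_allclose(twice.mz, once.mz, rtol=3e-6)


class TestResampling:
    def test_identity_when_already_on_grid(self):
        grid = default_grid(499.0, 501.0, 0.001)
        spec = _gaussian_spectrum(grid=grid)
        matrix = resample_to_grid([spec], grid)
        # matrix rows are float32; compare at single precision
        np.testing.assert_allclose(matrix.data[0], spec.intensity,
                                   rtol=1e-6, atol=1e-20)

    def test_finer_source_grid_preserves_apex(self):
        fine = default_grid(499.0, 501.0, 0.0005)
        spec = _gaussian_spectrum(grid=fine)
        coarse = default_grid(499.0, 501.0, 0.001)
        matrix = resample_to_grid([spec], coarse)
        assert matrix.data[0].max() == pytest.approx(100.0, rel=0.01)

    def test_shared_grid_across_native_grids(self):
        s1 = _gaussian_spectrum(grid=default_grid(499.0, 500.6, 0.001))
        s2 = _gaussian_spectrum(center=500.4,
                                grid=default_grid(499.4, 501.0, 0.0007))
        grid = default_grid(499.0, 501.0, 0.001)
        matrix = resample_to_grid([s1, s2], grid)
        assert matrix.data.shape == (2, grid.size)
        # outside native range -> zero
        assert matrix.data[0][-1] == 0.0
        assert matrix.data[1][0] == 0.0

    def test_empty_spectrum_rejected(self):
        grid = default_grid(499.0, 501.0, 0.01)
        with pytest.raises(ValueError, match="empty"):
            resample_to_grid(
                [MassSpectrum(np.empty(0), np.empty(0))], grid
            )


class TestPeakLookup:
    def test_peak_exactly_at_target(self):
        grid = default_grid(499.0, 501.0, 0.001)
        matrix = resample_to_grid([_gaussian_spectrum(grid=grid)], grid)
        assert peak_intensity(matrix, 500.0, 15.0)[0] == pytest.approx(
            100.0, rel=1e-3
        )

    def test_no_peak_returns_background_level(self):
        grid = default_grid(499.0, 501.0, 0.001)
        matrix = SpectralMatrix(grid=grid, data=np.full((1, grid.size), 3.0))
        assert peak_intensity(matrix, 500.0, 15.0)[0] == 3.0

    def test_two_peaks_in_window_returns_larger(self):
        grid = default_grid(499.0, 501.0, 0.001)
        data = np.zeros((1, grid.size))
        i = np.searchsorted(grid, 500.0)
        data[0, i - 2] = 40.0
        data[0, i + 2] = 90.0
        matrix = SpectralMatrix(grid=grid, data=data)
        assert peak_intensity(matrix, 500.0, 15.0)[0] == 90.0

    def test_window_without_grid_points(self):
        grid = default_grid(499.0, 501.0, 0.5)
        matrix = SpectralMatrix(grid=grid, data=np.zeros((1, grid.size)))
        with pytest.raises(ValueError, match="grid"):
            peak_intensity(matrix, 500.26, 1.0)
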