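"""Spectrum model, I/O and preprocessing chain."""

import numpy as np
import pytest

from ramanclear.exceptions import (
    AxisMismatchError,
    BandWindowError,
    DegenerateFitError,
    GroupingError,
    ParameterError,
    SpectrumParseError,
    SpectrumValidationError,
)
from ramanclear.spectra import (
    BandDefinition,
    RamanSpectrum,
    Region,
    average_replicates,
    band_intensity,
    baseline_subtract,
    estimate_baseline,
    pca_denoise,
    read_spectrum,
    resample_to_grid,
    smooth_savgol,
    write_spectrum,
)


def fp_spectrum(y, wn=None, **kw):
    if wn is None:
        wn = np.arange(400.0, 400.0 + len(y))
    return RamanSpectrum(wn, np.asarray(y, dtype=float), Region.FP, **kw)


class TestRamanSpectrum:
    def test_validates_axis_monotonicity_and_lengths(self):
        with pytest.raises(SpectrumValidationError):
            RamanSpectrum([500, 500, 501], [1, 2, 3], Region.FP)
        with pytest.raises(SpectrumValidationError):
            RamanSpectrum([500, 501], [1, 2, 3], Region.FP)
        with pytest.raises(SpectrumValidationError):
            RamanSpectrum([500.0], [1.0], Region.FP)

    def test_region_span_enforced(self):
        RamanSpectrum([400, 1800], [0, 0], Region.FP)  # boundary values allowed
        with pytest.raises(SpectrumValidationError):
            RamanSpectrum([300, 500], [0, 0], Region.FP)
        with pytest.raises(SpectrumValidationError):
            RamanSpectrum([2600, 3900], [0, 0], Region.HWN)

    def test_untreated_sentinel_distinct_from_time_zero(self):
        ref = fp_spectrum([1, 2, 3], time_s=None)
        t0 = fp_spectrum([1, 2, 3], time_s=0.0)
        assert ref.is_untreated and not t0.is_untreated


class TestReadSpectrum:
    def test_minimal_two_point_file(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("# comment\n400,10\n401,12\n")
        s = read_spectrum(p, Region.FP)
        assert len(s) == 2
        assert s.region is Region.FP
        np.testing.assert_allclose(s.intensities, [10, 12])

    def test_descending_rows_sorted_with_intensities(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("500\t7\n450\t3\n400\t1\n")
        s = read_spectrum(p, Region.FP)
        np.testing.assert_allclose(s.wavenumbers, [400, 450, 500])
        np.testing.assert_allclose(s.intensities, [1, 3, 7])

    def test_non_numeric_value_names_line(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("400 10\n401 oops\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(p, Region.FP)

    def test_too_few_points(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("400 10\n")
        with pytest.raises(SpectrumParseError):
            read_spectrum(p, Region.FP)

    def test_write_read_round_trip(self, tmp_path):
        s = fp_spectrum([1.5, 2.25, 3.125], depth_um=50, time_s=30, sample_id="a")
        write_spectrum(s, tmp_path / "s.txt")
        back = read_spectrum(tmp_path / "s.txt", Region.FP, 50, 30, "a")
        np.testing.assert_allclose(back.intensities, s.intensities)


class TestBaseline:
    def test_pure_polynomial_is_removed_entirely(self):
        wn = np.linspace(400, 1800, 500)
        y = 5.0 + 0.01 * wn + 2e-6 * wn**2
        s = RamanSpectrum(wn, y, Region.FP)
        out = baseline_subtract(s, poly_order=3)
        assert np.max(np.abs(out.intensities)) < 1e-8 * np.ptp(y)

    def test_peak_preserved_on_flat_baseline(self):
        wn = np.linspace(400, 1800, 1401)
        peak = 50.0 * np.exp(-((wn - 1000) ** 2) / (2 * 8.0**2))
        s = RamanSpectrum(wn, 100.0 + peak, Region.FP)
        out = baseline_subtract(s, poly_order=1)
        amp = out.intensities.max()
        assert abs(amp - 50.0) < 0.02 * 50.0

    def test_degenerate_order_raises(self):
        s = fp_spectrum([1, 2, 3])
        with pytest.raises(DegenerateFitError):
            baseline_subtract(s, poly_order=5)

    def test_anchor_quantile_validated(self):
        wn = np.linspace(400, 1800, 100)
        with pytest.raises(ParameterError):
            estimate_baseline(wn, np.ones(100), 2, anchor_quantile=0.0)


class TestSavgol:
    def test_reproduces_cubic_exactly(self):
        wn = np.linspace(400, 1800, 200)
        y = 1 + 2 * wn + 3e-3 * wn**2 - 1e-6 * wn**3
        out = smooth_savgol(RamanSpectrum(wn, y, Region.FP), 11, 3)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-10)

    def test_reduces_white_noise_variance(self, rng):
        wn = np.linspace(400, 1800, 1000)
        sds = []
        for _ in range(20):
            noise = rng.standard_normal(1000)
            out = smooth_savgol(RamanSpectrum(wn, 100 + noise, Region.FP), 11, 3)
            sds.append(np.std(out.intensities - 100))
        assert np.mean(sds) < 1.0  # sd of input noise

    @pytest.mark.parametrize("window,order", [(10, 3), (5, 7)])
    def test_invalid_parameters(self, window, order):
        s = fp_spectrum(np.ones(50))
        with pytest.raises(ParameterError):
            smooth_savgol(s, window, order)


class TestPcaDenoise:
    def test_full_rank_is_identity(self, rng):
        wn = np.linspace(400, 1800, 80)
        spectra = [
            RamanSpectrum(wn, rng.random(80), Region.FP) for _ in range(5)
        ]
        out = pca_denoise(spectra, n_components=4)
        for a, b in zip(out, spectra):
            np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-8)

    def test_rank_two_mixture_recovered_to_noise_floor(self, rng):
        wn = np.linspace(400, 1800, 300)
        b1 = np.exp(-((wn - 800) ** 2) / 800)
        b2 = np.exp(-((wn - 1400) ** 2) / 2000)
        clean = [
            10 * rng.random() * b1 + 10 * rng.random() * b2 for _ in range(12)
        ]
        sigma = 0.01
        noisy = [c + sigma * rng.standard_normal(300) for c in clean]
        out = pca_denoise(
            [RamanSpectrum(wn, y, Region.FP) for y in noisy], n_components=2
        )
        rms = np.sqrt(
            np.mean([(o.intensities - c) ** 2 for o, c in zip(out, clean)])
        )
        assert rms <= sigma

    def test_too_few_spectra(self):
        wn = np.linspace(400, 1800, 10)
        spectra = [RamanSpectrum(wn, np.ones(10), Region.FP)] * 2
        with pytest.raises(ParameterError):
            pca_denoise(spectra, n_components=3)

    def test_mismatched_axes(self):
        a = RamanSpectrum(np.linspace(400, 1800, 10), np.ones(10), Region.FP)
        b = RamanSpectrum(np.linspace(400, 1700, 10), np.ones(10), Region.FP)
        with pytest.raises(AxisMismatchError):
            pca_denoise([a, b, a, b], n_components=1)


class TestAverageReplicates:
    def test_singleton_and_arithmetic(self):
        y = np.array([1.0, 2.0, 4.0])
        s = fp_spectrum(y)
        assert np.array_equal(average_replicates([s]).intensities, y)
        out = average_replicates([s, fp_spectrum(3 * y)])
        np.testing.assert_allclose(out.intensities, 2 * y)

    def test_mixed_regions_rejected(self):
        a = RamanSpectrum([400, 500], [1, 1], Region.FP)
        b = RamanSpectrum([2600, 2700], [1, 1], Region.HWN)
        with pytest.raises(GroupingError):
            average_replicates([a, b])

    def test_mixed_depths_rejected(self):
        a = fp_spectrum([1, 2], depth_um=50)
        b = fp_spectrum([1, 2], depth_um=100)
        with pytest.raises(GroupingError):
            average_replicates([a, b])

    def test_commutes_with_smoothing(self, rng):
        wn = np.linspace(400, 1800, 200)
        ys = [rng.random(200) for _ in range(4)]
        spectra = [RamanSpectrum(wn, y, Region.FP) for y in ys]
        smooth_then_avg = average_replicates(
            [smooth_savgol(s, 11, 3) for s in spectra]
        )
        avg_then_smooth = smooth_savgol(average_replicates(spectra), 11, 3)
        np.testing.assert_allclose(
            smooth_then_avg.intensities, avg_then_smooth.intensities, atol=1e-12
        )


class TestBandIntensity:
    def test_gaussian_amplitude_recovered(self):
        wn = np.arange(400.0, 600.0)
        y = 7.0 * np.exp(-((wn - 485.0) ** 2) / (2 * 6.0**2))
        val = band_intensity(RamanSpectrum(wn, y, Region.FP), BandDefinition(485, 10))
        assert abs(val.intensity - 7.0) < 1e-6
        assert val.wavenumber_cm1 == 485.0

    def test_zero_spectrum(self):
        s = fp_spectrum(np.zeros(100))
        assert band_intensity(s, BandDefinition(450, 10)).intensity == 0.0

    def test_window_outside_axis(self):
        s = fp_spectrum(np.ones(100))
        with pytest.raises(BandWindowError):
            band_intensity(s, BandDefinition(2000, 10))


class TestResample:
    def test_linear_interpolation_on_linear_data(self):
        wn = np.array([400.0, 500.0, 600.0])
        s = RamanSpectrum(wn, 2 * wn, Region.FP)
        out = resample_to_grid(s, np.array([450.0, 550.0]))
        np.testing.assert_allclose(out.intensities, [900.0, 1100.0])

    def test_extrapolation_rejected(self):
        s = fp_spectrum([1, 2, 3])
        with pytest.raises(AxisMismatchError):
            resample_to_grid(s, np.array([300.0, 400.0]))


def test_full_chain_band_intensity_shift_below_two_percent():
    """Baseline + smoothing + full-rank PCA changes a clean band by < 2%."""
    wn = np.arange(400.0, 1801.0)
    amp = 80.0
    base = 20.0 + 0.005 * (wn - 400)
    peak = amp * np.exp(-((wn - 1003.0) ** 2) / (2 * 6.0**2))
    spectra = [
        RamanSpectrum(wn, base + (1 + 0.1 * k) * peak, Region.FP) for k in range(5)
    ]
    processed = [smooth_savgol(baseline_subtract(s, 5), 11, 3) for s in spectra]
    processed = pca_denoise(processed, n_components=4)
    got = band_intensity(processed[0], BandDefinition(1003, 10)).intensity
    assert abs(got - amp) < 0.02 * amp
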