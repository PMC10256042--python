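"""Burg AR estimation, AR spectra, band integration, sliding trend."""

import numpy as np
import pytest

from hrvdx.preprocess import UniformSeries
from hrvdx.spectral import (
    ARModel,
    HF_BAND,
    LF_BAND,
    ar_psd,
    band_power,
    default_order,
    fit_burg,
    psd_grid,
    spectral_trend,
)


def simulate_ar1(phi, n, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    e = rng.normal(0, sigma, n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


class TestFitBurg:
    def test_ar1_recovery_matches_yule_walker_oracle(self):
        x = simulate_ar1(0.9, 1000, seed=11)
        model = fit_burg(x, order=1)
        phi_burg = -model.coefficients[0]
        # independent oracle: Yule-Walker estimate from sample autocovariance
        xc = x - x.mean()
        phi_yw = np.dot(xc[1:], xc[:-1]) / np.dot(xc, xc)
        assert phi_burg == pytest.approx(0.9, abs=0.05)
        assert phi_burg == pytest.approx(phi_yw, abs=0.02)

    def test_white_noise_coefficients_small(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=5000)
            model = fit_burg(x, order=6)
            assert np.max(np.abs(model.coefficients)) < 0.1

    def test_constant_input_degenerate(self):
        model = fit_burg(np.full(100, 7.0), order=4)
        assert model.degenerate
        assert model.noise_variance == 0.0

    def test_reflection_coefficients_stable(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            t = np.arange(37) / 1.25
            x = 30 * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 3, 37)
            model = fit_burg(x, order=default_order(37), fs_hz=1.25)
            assert np.all(np.abs(model.reflection) <= 1.0)

    def test_order_too_high_raises(self):
        with pytest.raises(ValueError, match="order"):
            fit_burg(np.arange(10.0), order=5)


class TestArPsd:
    def test_white_noise_flat_spectrum_integrates_to_variance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3.0, 4000)
        model = fit_burg(x, order=1, fs_hz=2.0)
        f = psd_grid(model)
        psd = ar_psd(model, f)
        total = np.trapezoid(psd, f)
        assert total == pytest.approx(np.var(x), rel=0.02)

    def test_ar2_resonance_peak_location(self):
        # poles at radius 0.95, angle pi/2 -> analytic peak exactly at fs/4
        r, f0, fs = 0.95, 0.25, 1.0
        w0 = 2 * np.pi * f0 / fs
        coeffs = np.array([-2 * r * np.cos(w0), r**2])
        model = ARModel(order=2, coefficients=coeffs, noise_variance=1.0, fs_hz=fs,
                        reflection=np.array([coeffs[0] / (1 + coeffs[1]), coeffs[1]]))
        f = psd_grid(model)
        psd = ar_psd(model, f)
        assert abs(f[np.argmax(psd)] - f0) < 0.01

    def test_parseval_for_fitted_windows(self):
        rng = np.random.default_rng(4)
        fs = 1.25
        t = np.arange(38) / fs
        for amp in (10, 30, 60):
            x = amp * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 3, t.size)
            model = fit_burg(x, order=default_order(t.size), fs_hz=fs)
            f = psd_grid(model)
            total = np.trapezoid(ar_psd(model, f), f)
            assert total == pytest.approx(np.var(x - x.mean()), rel=0.02)

    def test_grid_outside_nyquist_rejected(self):
        model = fit_burg(np.random.default_rng(0).normal(size=100), 2, fs_hz=1.0)
        with pytest.raises(ValueError):
            ar_psd(model, np.array([0.6]))


class TestBandPower:
    def test_sinusoid_power_lands_in_hf_band(self):
        rng = np.random.default_rng(6)
        fs = 1.25
        t = np.arange(38) / fs
        x = 30 * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 2, t.size)
        model = fit_burg(x, order=default_order(t.size), fs_hz=fs)
        f = psd_grid(model)
        psd = ar_psd(model, f)
        hf = band_power(psd, f, HF_BAND)
        lf = band_power(psd, f, LF_BAND)
        assert hf == pytest.approx(450.0, rel=0.15)
        assert hf / (hf + lf) >= 0.9
        assert lf < 0.1 * hf

    def test_zero_signal_zero_power(self):
        model = fit_burg(np.zeros(100), order=3, fs_hz=1.25)
        f = psd_grid(model)
        assert band_power(ar_psd(model, f), f, HF_BAND) == 0.0

    def test_doubling_amplitude_quadruples_power(self):
        fs = 1.25
        t = np.arange(38) / fs
        rng = np.random.default_rng(8)
        noise = rng.normal(0, 1, t.size)
        powers = []
        for amp in (15, 30):
            x = amp * np.sin(2 * np.pi * 0.25 * t) + noise
            model = fit_burg(x, order=default_order(t.size), fs_hz=fs)
            f = psd_grid(model)
            powers.append(band_power(ar_psd(model, f), f, HF_BAND))
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.2)

    def test_inverted_band_rejected(self):
        f = np.linspace(0, 0.5, 100)
        with pytest.raises(ValueError, match="inverted"):
            band_power(np.ones_like(f), f, (0.4, 0.15))


class TestSpectralTrend:
    def test_estimate_count_60s(self):
        u = UniformSeries(values_ms=800 + np.random.default_rng(0).normal(0, 5, 75), fs_hz=1.25)
        trend = spectral_trend(u)
        assert len(trend) == 16
        np.testing.assert_allclose(trend.t_s, np.arange(30, 61, 2))

    def test_estimate_count_220s_paradigm(self):
        n = int(220 * 1.25)
        u = UniformSeries(values_ms=800 + np.random.default_rng(1).normal(0, 5, n), fs_hz=1.25)
        trend = spectral_trend(u)
        assert len(trend) == 96

    def test_stationary_input_stable_hf(self):
        rng = np.random.default_rng(12)
        fs = 1.25
        t = np.arange(int(220 * fs)) / fs
        u = UniformSeries(values_ms=800 + 30 * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 3, t.size), fs_hz=fs)
        trend = spectral_trend(u)
        cv = np.std(trend.hf_ms2) / np.mean(trend.hf_ms2)
        assert cv < 0.5

    def test_sum_identity_and_nonnegativity(self):
        rng = np.random.default_rng(13)
        u = UniformSeries(values_ms=800 + rng.normal(0, 10, 100), fs_hz=1.25)
        trend = spectral_trend(u)
        assert np.all(trend.lf_ms2 >= 0) and np.all(trend.hf_ms2 >= 0)
        np.testing.assert_allclose(trend.lfhf_sum_ms2, trend.lf_ms2 + trend.hf_ms2)

    def test_too_short_recording_raises(self):
        u = UniformSeries(values_ms=np.full(20, 800.0), fs_hz=1.25)
        with pytest.raises(ValueError):
            spectral_trend(u)
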