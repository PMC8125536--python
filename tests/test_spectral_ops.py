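"""Difference arithmetic, fraction estimation, radical removal, quantification."""

import numpy as np
import pytest

from oecspin import (
    IllConditionedError, Spectrum, SynthConfig, ValidationError,
    align_spectra, difference_spectrum, double_integral,
    estimate_conversion_fraction, generate_experiment, remove_radical,
    scaled_subtract,
)
from tests.conftest import X_BAND


def flat_spec(axis, y):
    return Spectrum(axis, y, X_BAND)


@pytest.fixture
def axis():
    return np.linspace(2400.0, 4400.0, 2000)


class TestDifferenceAndScaling:
    def test_identical_spectra_give_zero(self, axis):
        a = flat_spec(axis, np.sin(axis / 100.0))
        d = difference_spectrum(a, a)
        assert np.all(d.intensity == 0.0)

    def test_recovers_injected_template_exactly(self, axis):
        bg = flat_spec(axis, np.cos(axis / 57.0))
        template = np.exp(-((axis - 3300.0) / 150.0) ** 2)
        light = flat_spec(axis, bg.intensity + template)
        np.testing.assert_allclose(difference_spectrum(light, bg).intensity,
                                   template, atol=1e-10)

    def test_offset_axes_require_alignment(self, axis):
        a = flat_spec(axis, np.zeros(axis.size))
        b = flat_spec(axis + 0.5 * (axis[1] - axis[0]), np.zeros(axis.size))
        with pytest.raises(ValidationError):
            difference_spectrum(a, b)
        aligned = align_spectra([a, b])
        assert difference_spectrum(*aligned) is not None

    def test_scaled_subtract_identities(self, axis):
        b = flat_spec(axis, np.sin(axis / 90.0))
        pure = np.exp(-((axis - 3000.0) / 200.0) ** 2)
        a = flat_spec(axis, pure + 0.65 * b.intensity)
        assert np.all(scaled_subtract(a, b, 0.0).intensity == a.intensity)
        np.testing.assert_allclose(scaled_subtract(b, b, 1.0).intensity, 0.0,
                                   atol=1e-15)
        np.testing.assert_allclose(scaled_subtract(a, b, 0.65).intensity, pure,
                                   atol=1e-10)

    def test_out_of_range_fraction_warns(self, axis):
        a = flat_spec(axis, np.ones(axis.size))
        with pytest.warns(UserWarning, match="fraction"):
            scaled_subtract(a, a, 2.0)

    def test_linearity(self, axis):
        rng = np.random.default_rng(5)
        a = flat_spec(axis, rng.normal(size=axis.size))
        b = flat_spec(axis, rng.normal(size=axis.size))
        c = 3.7
        lhs = difference_spectrum(a.with_intensity(c * a.intensity),
                                  b.with_intensity(c * b.intensity)).intensity
        rhs = c * difference_spectrum(a, b).intensity
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestConversionFraction:
    def test_constructed_fractions(self, axis):
        ml = np.sin(axis / 40.0) * np.exp(-((axis - 3400.0) / 700.0) ** 2)
        d240 = flat_spec(axis, ml)
        d140 = flat_spec(axis, 0.65 * ml)
        f, resid = estimate_conversion_fraction(d240, d140, (2400.0, 4400.0))
        assert f == pytest.approx(0.35, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)
        f0, _ = estimate_conversion_fraction(d240, d240, (2400.0, 4400.0))
        assert f0 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_reference_raises(self, axis):
        zero = flat_spec(axis, np.zeros(axis.size))
        with pytest.raises(IllConditionedError):
            estimate_conversion_fraction(zero, zero, (2400.0, 4400.0))

    def test_monte_carlo_recovery_snr50(self):
        errs = []
        for seed in range(30):
            cfg = SynthConfig(seed=seed, noise_sd=0.02)   # SNR 50 on unit ML
            exp = generate_experiment(cfg)
            d240 = difference_spectrum(exp.illuminated_240K, exp.annealed)
            d140 = difference_spectrum(exp.illuminated_140K_NIR, exp.annealed)
            f, _ = estimate_conversion_fraction(d240, d140)
            errs.append(f - exp.truth["fraction"])
        assert np.max(np.abs(errs)) <= 0.02

    def test_unbiased_at_high_snr(self):
        errs = []
        for seed in range(100):
            cfg = SynthConfig(seed=seed, noise_sd=0.005)  # SNR 200
            exp = generate_experiment(cfg)
            d240 = difference_spectrum(exp.illuminated_240K, exp.annealed)
            d140 = difference_spectrum(exp.illuminated_140K_NIR, exp.annealed)
            f, _ = estimate_conversion_fraction(d240, d140)
            errs.append(f - exp.truth["fraction"])
        assert abs(np.mean(errs)) < 0.005

    def test_window_invariance_noiseless(self):
        cfg = SynthConfig(seed=0, noise_sd=0.0)
        exp = generate_experiment(cfg)
        d240 = difference_spectrum(exp.illuminated_240K, exp.annealed)
        d140 = difference_spectrum(exp.illuminated_140K_NIR, exp.annealed)
        f_full, _ = estimate_conversion_fraction(d240, d140, (2400.0, 4400.0))
        f_half, _ = estimate_conversion_fraction(d240, d140, (2400.0, 3400.0))
        assert abs(f_full - f_half) < 0.02


class TestRemoveRadical:
    def test_fit_mode_removes_injected_line(self):
        axis = np.linspace(3000.0, 3700.0, 1400)
        b0, sigma, amp = 3339.0, 4.0, 1.0
        x = (axis - b0) / sigma
        line = -amp * x * np.exp(-x ** 2 / 2)
        spec = flat_spec(axis, line)
        out = remove_radical(spec, (3300.0, 3380.0), mode="fit")
        assert np.max(np.abs(out.intensity)) <= 0.01 * amp

    def test_interpolate_mode_flattens_window(self):
        axis = np.linspace(3000.0, 3700.0, 1400)
        x = (axis - 3339.0) / 4.0
        spec = flat_spec(axis, -x * np.exp(-x ** 2 / 2))
        out = remove_radical(spec, (3300.0, 3380.0), mode="interpolate")
        mask = out.window_mask((3305.0, 3375.0))
        assert np.max(np.abs(out.intensity[mask])) <= 1e-6

    def test_no_radical_leaves_spectrum_unchanged(self):
        axis = np.linspace(3000.0, 3700.0, 1400)
        spec = flat_spec(axis, np.zeros(axis.size))
        out = remove_radical(spec, (3300.0, 3380.0), mode="fit")
        assert np.max(np.abs(out.intensity)) <= 1e-12

    def test_wide_window_warns(self):
        axis = np.linspace(3000.0, 3700.0, 1400)
        spec = flat_spec(axis, np.zeros(axis.size))
        with pytest.warns(UserWarning, match="20%"):
            remove_radical(spec, (3100.0, 3600.0), mode="interpolate")


class TestDoubleIntegral:
    def test_gaussian_derivative_closed_form(self):
        axis = np.linspace(1000.0, 2300.0, 2600)
        amp_abs, sigma, b0 = 2.0, 40.0, 1650.0
        x = (axis - b0) / sigma
        deriv = -amp_abs * x / sigma * np.exp(-x ** 2 / 2)
        spec = flat_spec(axis, deriv)
        area = double_integral(spec, (1200.0, 2100.0))
        assert area == pytest.approx(amp_abs * sigma * np.sqrt(2 * np.pi),
                                     rel=0.005)

    def test_zero_and_linearity(self):
        axis = np.linspace(1000.0, 2000.0, 1000)
        zero = flat_spec(axis, np.zeros(axis.size))
        assert double_integral(zero, (1100.0, 1900.0)) == 0.0
        rng = np.random.default_rng(2)
        y = rng.normal(size=axis.size)
        a1 = double_integral(flat_spec(axis, y), (1100.0, 1900.0))
        a3 = double_integral(flat_spec(axis, 3.0 * y), (1100.0, 1900.0))
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_stability_under_window_changes_for_compact_signal(self):
        # a localized g4.1-like derivative feature: the quantification is
        # insensitive to +-10% window-edge changes when the edges sit in
        # signal-free baseline
        axis = np.linspace(400.0, 2900.0, 2500)
        x = (axis - 1633.0) / 150.0
        spec = flat_spec(axis, -x * np.exp(-x ** 2 / 2))
        areas = [double_integral(spec, (600.0 * s, 2700.0 * t))
                 for s, t in ((0.9, 1.1), (1.0, 1.0), (1.1, 0.9))]
        assert areas[1] > 0
        assert np.ptp(areas) <= 0.03 * abs(areas[1])

    def test_simulated_g41_template_area_positive(self):
        cfg = SynthConfig(seed=3, noise_sd=0.0)
        exp = generate_experiment(cfg)
        spec = flat_spec(exp.annealed.field_G, exp.truth["g41_template"])
        assert double_integral(spec, (450.0, 2880.0)) > 0


class TestAlign:
    def test_identity_when_axes_equal(self, axis):
        a = flat_spec(axis, np.sin(axis / 70.0))
        out = align_spectra([a, a])
        np.testing.assert_allclose(out[0].intensity, a.intensity)
        assert "resampled" not in out[0].metadata

    def test_half_step_shift_interpolates_analytic_line(self):
        axis = np.linspace(1000.0, 2000.0, 2001)
        step = axis[1] - axis[0]
        f = lambda b: np.sin(b / 200.0)
        a = flat_spec(axis, f(axis))
        b = flat_spec(axis + step / 2.0, f(axis + step / 2.0))
        out = align_spectra([a, b])
        np.testing.assert_allclose(out[1].intensity, f(out[1].field_G), atol=1e-6)
        assert out[1].metadata.get("resampled")

    def test_disjoint_ranges_raise(self):
        a = flat_spec(np.linspace(1000.0, 2000.0, 100), np.zeros(100))
        b = flat_spec(np.linspace(3000.0, 4000.0, 100), np.zeros(100))
        with pytest.raises(ValidationError):
            align_spectra([a, b])
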