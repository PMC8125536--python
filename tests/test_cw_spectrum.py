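"""Powder simulation, resonance search and effective-g extraction."""

import numpy as np
import pytest

from oecspin import (
    GHZ_TO_CM, G_TO_CM,
    DomainError, SignalNotFoundError, SpinSystem, Spectrum,
    build_hamiltonian, doublet_effective_g, effective_g, field_for_g,
    locate_dominant_extremum, locate_signal_center, orientation_grid,
    powder_spectrum, resonance_search,
)
from tests.conftest import X_BAND


class TestEffectiveG:
    def test_closed_form_values(self):
        assert effective_g(3347.0, X_BAND) == pytest.approx(2.000, abs=2e-3)
        assert effective_g(1633.0, X_BAND) == pytest.approx(4.10, abs=0.01)

    def test_round_trip(self):
        for g in (0.6, 2.0, 4.3, 9.7):
            assert effective_g(field_for_g(g, X_BAND), X_BAND) == \
                pytest.approx(g, rel=1e-10)

    def test_nonpositive_field_rejected(self):
        with pytest.raises(DomainError):
            effective_g(-10.0, X_BAND)


class TestDoubletEffectiveG:
    def test_rhombic_s52_middle_doublet_isotropic(self):
        sys = SpinSystem(S=2.5, D=2.0, E=2.0 / 3.0, g_principal=(2.0,) * 3)
        gxyz = doublet_effective_g(sys, 1)
        assert max(gxyz) - min(gxyz) <= 0.01
        assert np.mean(gxyz) == pytest.approx(30.0 / 7.0, abs=1e-3)

    def test_rhombic_s52_outer_doublets_principal_set(self):
        sys = SpinSystem(S=2.5, D=2.0, E=2.0 / 3.0, g_principal=(2.0,) * 3)
        vals = sorted(set(round(v, 3)
                          for k in (0, 2) for v in doublet_effective_g(sys, k)))
        # outer doublets share the anisotropic principal set
        assert vals == pytest.approx([0.607, 0.857, 9.678], abs=2e-3)

    def test_axial_s32_half_doublet(self):
        sys = SpinSystem(S=1.5, D=2.0, E=0.0, g_principal=(2.0,) * 3)
        gx, gy, gz = doublet_effective_g(sys, 0)
        assert (gx, gy) == pytest.approx((4.0, 4.0), abs=1e-6)
        assert gz == pytest.approx(2.0, abs=1e-6)

    def test_axial_limit_of_s32_doublets(self):
        # E/D -> 0 reproduces (2g_perp, 2g_perp, g_par) for the +-1/2 doublet
        gperp, gpar = 2.05, 1.95
        sys = SpinSystem(S=1.5, D=3.0, E=3e-4, g_principal=(gperp, gperp, gpar))
        gx, gy, gz = doublet_effective_g(sys, 0)
        assert gx == pytest.approx(2 * gperp, rel=1e-3)
        assert gy == pytest.approx(2 * gperp, rel=1e-3)
        assert gz == pytest.approx(gpar, rel=1e-3)

    def test_index_out_of_range(self):
        sys = SpinSystem(S=1.5, D=2.0)
        with pytest.raises(DomainError):
            doublet_effective_g(sys, 2)

    def test_low_zfs_regime_warns(self):
        sys = SpinSystem(S=2.5, D=0.45, E=0.1125)
        with pytest.warns(UserWarning, match="5 hv"):
            doublet_effective_g(sys, 1)


class TestResonanceSearch:
    def test_spin_half_single_resonance_closed_form(self):
        sys = SpinSystem(S=0.5, g_principal=(2.0,) * 3)
        ts = resonance_search(sys, (0, 0, 1), X_BAND, (100.0, 5000.0))
        assert len(ts) == 1
        b = ts.field_G[0]
        assert b == pytest.approx(X_BAND * GHZ_TO_CM / (2.0 * G_TO_CM), abs=0.01)
        # resonance condition satisfied to 1e-6 relative
        e = np.linalg.eigvalsh(build_hamiltonian(sys, (0, 0, b)))
        assert abs((e[1] - e[0]) - X_BAND * GHZ_TO_CM) <= 1e-6 * X_BAND * GHZ_TO_CM

    def test_s32_parallel_field_g2_transition_only(self):
        # D >> hν along z: the only strong transition is the intradoublet
        # -1/2 <-> +1/2 line near g ~ 2
        sys = SpinSystem(S=1.5, D=2.0, g_principal=(2.0,) * 3)
        ts = resonance_search(sys, (0, 0, 1), X_BAND, (200.0, 6000.0))
        dominant = ts.field_G[np.argmax(ts.amplitude)]
        assert effective_g(dominant, X_BAND) == pytest.approx(2.0, abs=0.01)

    def test_s32_perpendicular_field_g4_transition(self):
        sys = SpinSystem(S=1.5, D=2.0, g_principal=(2.0,) * 3)
        ts = resonance_search(sys, (1, 0, 0), X_BAND, (200.0, 6000.0))
        dominant = ts.field_G[np.argmax(ts.amplitude)]
        assert effective_g(dominant, X_BAND) == pytest.approx(4.0, abs=0.05)

    def test_empty_window_is_not_an_error(self):
        sys = SpinSystem(S=0.5, g_principal=(2.0,) * 3)
        ts = resonance_search(sys, (0, 0, 1), X_BAND, (100.0, 500.0))
        assert len(ts) == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(DomainError):
            resonance_search(SpinSystem(S=0.5), (0, 0, 1), X_BAND, (500.0, 100.0))


class TestPowderSpectrum:
    def test_isotropic_spin_half_line_at_closed_form_field(self):
        sys = SpinSystem(S=0.5, g_principal=(2.0,) * 3)
        axis = np.linspace(3000.0, 3700.0, 1400)
        spec = powder_spectrum(sys, X_BAND, axis, n_orientations=200, linewidth_G=20.0)
        center = locate_signal_center(spec, (3100.0, 3600.0))
        assert abs(center - field_for_g(2.0, X_BAND)) <= spec.step_G

    def test_absorption_integral_invariant_under_linewidth(self):
        sys = SpinSystem(S=0.5, g_principal=(2.0,) * 3)
        axis = np.linspace(2900.0, 3800.0, 1800)
        areas = []
        for lw in (15.0, 30.0, 60.0):
            absn = powder_spectrum(sys, X_BAND, axis, n_orientations=200,
                                   linewidth_G=lw, derivative=False)
            areas.append(np.trapezoid(absn.intensity, axis))
        assert np.ptp(areas) <= 0.005 * np.mean(areas)

    def test_orientation_grid_convergence(self):
        sys = SpinSystem(S=1.5, D=2.0, E=0.3, g_principal=(2.0,) * 3)
        axis = np.linspace(1000.0, 4000.0, 600)
        specs = {n: powder_spectrum(sys, X_BAND, axis, n_orientations=n,
                                    linewidth_G=60.0).intensity
                 for n in (200, 400, 800, 1600)}
        rms = [np.sqrt(np.mean((specs[n] - specs[2 * n]) ** 2))
               for n in (200, 400, 800)]
        assert rms[0] > rms[1] > rms[2]

    def test_frequency_covariance_for_zero_zfs(self):
        # for D = 0, simulating at 2ν on a doubled field axis is congruent
        sys = SpinSystem(S=0.5, g_principal=(2.1, 2.0, 1.9), temperature=300.0)
        axis = np.linspace(2800.0, 3800.0, 1000)
        s1 = powder_spectrum(sys, X_BAND, axis, n_orientations=300, linewidth_G=30.0)
        s2 = powder_spectrum(sys, 2 * X_BAND, 2 * axis, n_orientations=300,
                             linewidth_G=60.0)
        a, b = s1.intensity, s2.intensity
        corr = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert corr > 0.999

    def test_boltzmann_weighting_favors_lower_doublet_when_cold(self):
        # rhombic S = 5/2: compare the ground-doublet line (g_eff ~ 10, low
        # field) against the middle-doublet line for the same orientation
        sys = SpinSystem(S=2.5, D=0.45, E=0.1125, g_principal=(2.0,) * 3)

        def doublet_amp_ratio(temp):
            ts = resonance_search(sys, (0, 1, 0), X_BAND, (200.0, 2500.0),
                                  temperature_K=temp)
            low = ts.amplitude[(ts.lower == 0) & (ts.upper == 1)].sum()
            mid = ts.amplitude[(ts.lower == 2) & (ts.upper == 3)].sum()
            assert low > 0 and mid > 0
            return low / mid

        # interdoublet gap ~1.17 cm^-1 -> expected cold enhancement of the
        # ground-doublet line ~ e^(gap/kT) ~ 1.3 at 6 K, ~1 when populations
        # equalize at high temperature
        assert doublet_amp_ratio(6.0) > 1.2 * doublet_amp_ratio(6000.0)

    def test_perturbative_hyperfine_matches_exact(self, table1_52):
        axis = np.linspace(400.0, 2900.0, 625)
        kw = dict(n_orientations=60, linewidth_G=140.0, n_field_steps=48)
        pert = powder_spectrum(table1_52, X_BAND, axis, hyperfine="perturbative", **kw)
        exact = powder_spectrum(table1_52, X_BAND, axis, hyperfine="exact", **kw)
        scale = np.ptp(exact.intensity)
        assert np.sqrt(np.mean((pert.intensity - exact.intensity) ** 2)) <= 0.05 * scale
        b_p = locate_dominant_extremum(pert, (1000.0, 2400.0), which="min")
        b_e = locate_dominant_extremum(exact, (1000.0, 2400.0), which="min")
        assert abs(b_p - b_e) <= 20.0

    def test_validation_errors(self):
        sys = SpinSystem(S=0.5)
        with pytest.raises(DomainError):
            powder_spectrum(sys, X_BAND, np.linspace(1000, 2000, 100),
                            n_orientations=10, linewidth_G=20.0)
        with pytest.raises(Exception):
            powder_spectrum(sys, X_BAND, np.array([1.0, 2.0, 10.0]),
                            n_orientations=100, linewidth_G=20.0)


class TestOrientationGrid:
    def test_weights_normalized_and_vectors_unit(self):
        v, w = orientation_grid(300)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(v >= -1e-12)  # one octant


class TestLocateSignalCenter:
    def _line(self, center, axis, sigma=20.0, amp=1.0, noise=None):
        x = (axis - center) / sigma
        y = -amp * x * np.exp(-x ** 2 / 2)
        if noise is not None:
            y = y + noise
        return Spectrum(axis, y, X_BAND)

    def test_symmetric_line_center(self):
        axis = np.linspace(1000.0, 2300.0, 1300)
        spec = self._line(1650.0, axis)
        assert abs(locate_signal_center(spec, (1200.0, 2100.0)) - 1650.0) <= \
            spec.step_G

    def test_two_features_isolated_by_windows(self):
        axis = np.linspace(1000.0, 3000.0, 2000)
        x1 = (axis - 1500.0) / 20.0
        x2 = (axis - 2500.0) / 20.0
        y = -x1 * np.exp(-x1 ** 2 / 2) - 0.7 * x2 * np.exp(-x2 ** 2 / 2)
        spec = Spectrum(axis, y, X_BAND)
        assert abs(locate_signal_center(spec, (1200.0, 1900.0)) - 1500.0) <= 1.1
        assert abs(locate_signal_center(spec, (2100.0, 2900.0)) - 2500.0) <= 1.1

    def test_noisy_center_within_half_step_of_truth(self):
        axis = np.linspace(1000.0, 2300.0, 1300)
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            noise = rng.normal(0, 1.0 / 20.0, axis.size)  # SNR 20 on unit amp
            spec = self._line(1650.0, axis, noise=noise)
            errs.append(locate_signal_center(spec, (1500.0, 1800.0)) - 1650.0)
        assert np.median(np.abs(errs)) <= 0.5 * (axis[1] - axis[0])

    def test_no_sign_change_raises(self):
        axis = np.linspace(1000.0, 2000.0, 500)
        spec = Spectrum(axis, np.ones(axis.size), X_BAND)
        with pytest.raises(SignalNotFoundError):
            locate_signal_center(spec, (1200.0, 1800.0))
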