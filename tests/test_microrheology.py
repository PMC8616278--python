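"""Micro-rheology chain: PSD, exponent fit, FDT, Kramers--Kronig, GSER."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import Boltzmann as K_B

from escmech.errors import DataError, ParameterError, StateError
from escmech.io import load_trajectory, save_trajectory
from escmech.microrheology import (ComplexResponse, PowerSpectrum,
                                   TrajectoryRecord, classify_regime,
                                   compute_msd, compute_psd,
                                   fit_scaling_exponent,
                                   imag_response_from_psd,
                                   kramers_kronig_real, log_band_average,
                                   moduli_from_trajectory, shear_moduli,
                                   subtract_trap)
from escmech.synthetic import (simulate_brownian_trajectory,
                               simulate_power_law_trajectory,
                               simulate_trapped_viscous_trajectory)

FS = 22000.0


def _exact_power_spectrum(alpha, prefactor=1.0, n=4096):
    freq = np.arange(1, n + 1) * FS / (2.0 * n)
    return PowerSpectrum(freq, prefactor * freq ** -(1.0 + alpha),
                         n_segments=1, nyquist=FS / 2)


class TestComputePsd:
    def test_sinusoid_has_single_dominant_bin(self):
        n = 2**14
        f0 = round(1000.0 * n / FS) * FS / n  # bin-centered, no leakage
        t = np.arange(n) / FS
        tr = TrajectoryRecord(np.sin(2 * np.pi * f0 * t), FS)
        spec = compute_psd(tr, segment_length=n, overlap_fraction=0.0,
                           window="boxcar")
        peak = spec.frequency[np.argmax(spec.psd)]
        assert abs(peak - f0) < spec.frequency[0]
        assert spec.psd.max() > 100 * np.sort(spec.psd)[-2]

    def test_parseval_for_unwindowed_single_segment(self, rng):
        x = rng.standard_normal(2**12)
        tr = TrajectoryRecord(x, FS)
        spec = compute_psd(tr, segment_length=x.size, overlap_fraction=0.0,
                           window="boxcar")
        df = spec.frequency[1] - spec.frequency[0]
        assert np.sum(spec.psd) * df == pytest.approx(np.var(x), rel=1e-6)

    def test_segment_length_longer_than_series_is_an_error(self, rng):
        tr = TrajectoryRecord(rng.standard_normal(100), FS)
        with pytest.raises(ParameterError):
            compute_psd(tr, segment_length=200)


class TestFitScalingExponent:
    def test_inverse_square_grid_gives_alpha_one(self):
        # log-binned band averages leave a curvature residual ~1e-3
        fit = fit_scaling_exponent(_exact_power_spectrum(1.0))
        assert fit.alpha == pytest.approx(1.0, abs=0.01)
        assert fit.regime == "brownian"

    def test_known_prefactor_and_exponent(self):
        fit = fit_scaling_exponent(_exact_power_spectrum(0.5, prefactor=7.0))
        assert fit.alpha == pytest.approx(0.5, abs=0.01)
        assert fit.prefactor == pytest.approx(7.0, rel=0.05)

    @settings(deadline=None, max_examples=20)
    @given(alpha=st.floats(0.1, 1.5))
    def test_exact_grid_recovery_is_a_fixed_point(self, alpha):
        fit = fit_scaling_exponent(_exact_power_spectrum(alpha))
        assert fit.alpha == pytest.approx(alpha, abs=0.01)

    def test_band_outside_spectrum_is_an_error(self):
        with pytest.raises(ParameterError):
            fit_scaling_exponent(_exact_power_spectrum(1.0), band=(2e4, 3e4))

    def test_nonpositive_psd_in_band_is_an_error(self):
        spec = _exact_power_spectrum(1.0)
        spec.psd[600] = 0.0
        with pytest.raises(DataError):
            fit_scaling_exponent(spec)


class TestClassifyRegime:
    @pytest.mark.parametrize("alpha,regime", [
        (0.48, "subdiffusive"), (1.0, "brownian"), (1.04, "brownian"),
        (1.3, "superdiffusive"), (0.1, "subdiffusive")])
    def test_regimes(self, alpha, regime):
        assert classify_regime(alpha) == regime

    def test_nonfinite_alpha_is_an_error(self):
        with pytest.raises(ParameterError):
            classify_regime(float("nan"))


class TestImagResponse:
    def test_flat_psd_gives_linear_chi(self):
        freq = np.linspace(10, 1000, 100)
        c = 5.0  # nm^2/Hz, one-sided
        spec = PowerSpectrum(freq, np.full(100, c), 1, FS / 2)
        resp = imag_response_from_psd(spec, temperature_K=300.0)
        # FDT with the two-sided density c/2 (SI units)
        expected_slope = np.pi * (c * 1e-18 / 2.0) / (K_B * 300.0)
        slope = resp.chi_imag / freq
        assert np.allclose(slope, expected_slope, rtol=1e-12)

    def test_zero_psd_gives_zero_response(self):
        spec = PowerSpectrum(np.linspace(1, 100, 50), np.zeros(50), 1, FS / 2)
        resp = imag_response_from_psd(spec, 300.0)
        assert np.all(resp.chi_imag == 0)

    def test_missing_temperature_is_an_error(self):
        spec = _exact_power_spectrum(1.0)
        with pytest.raises(ParameterError):
            imag_response_from_psd(spec, temperature_K=None)

    def test_ou_response_matches_harmonic_trap_closed_form(self):
        k, eta, r, T = 2e-6, 1e-3, 0.25e-6, 300.0
        tr, _ = simulate_trapped_viscous_trajectory(k, eta, r, T, 2**19, FS,
                                                    seed=11)
        spec = compute_psd(tr, 4096)
        resp = imag_response_from_psd(spec, T)
        gamma = 6 * np.pi * eta * r
        w = 2 * np.pi * spec.frequency
        expected = w * gamma / (k**2 + (w * gamma) ** 2)
        sel = (spec.frequency > 50) & (spec.frequency < 2000)
        ratio = resp.chi_imag[sel].mean() / expected[sel].mean()
        assert abs(ratio - 1.0) < 0.05


class TestKramersKronig:
    def _lorentzian(self, fc, fmax=11000.0, df=2.0):
        f = np.arange(df, fmax + df, df)
        a, b = 1.0, 1.0 / fc
        chi2 = b * f / (a**2 + (b * f) ** 2)
        exact = a / (a**2 + (b * f) ** 2)
        return f, chi2, exact

    def test_lorentzian_pair_within_three_percent_in_valid_range(self):
        f, chi2, exact = self._lorentzian(fc=200.0)
        out = kramers_kronig_real(
            ComplexResponse(f, chi2, kk_valid_max=1100.0))
        rel = np.abs(out.chi_real - exact) / exact
        assert rel[f <= 1100.0].max() < 0.03

    def test_error_grows_above_a_tenth_of_the_grid_maximum(self):
        f, chi2, exact = self._lorentzian(fc=200.0)
        out = kramers_kronig_real(ComplexResponse(f, chi2, kk_valid_max=1100.0))
        rel = np.abs(out.chi_real - exact) / exact
        assert rel[(f > 3000)].max() > 3 * rel[f <= 1100.0].max()

    def test_zero_imaginary_part_gives_zero_real_part(self):
        f = np.linspace(1, 1000, 500)
        out = kramers_kronig_real(ComplexResponse(f, np.zeros(500)))
        assert np.allclose(out.chi_real, 0.0)

    def test_grid_refinement_changes_little_in_valid_range(self):
        f1, chi1, _ = self._lorentzian(fc=200.0, df=4.0)
        f2, chi2, _ = self._lorentzian(fc=200.0, df=2.0)
        out1 = kramers_kronig_real(ComplexResponse(f1, chi1))
        out2 = kramers_kronig_real(ComplexResponse(f2, chi2))
        coarse_on_fine = np.interp(f1[f1 <= 1100], f2, out2.chi_real)
        rel = np.abs(out1.chi_real[f1 <= 1100] - coarse_on_fine) / coarse_on_fine
        assert rel.max() < 0.01


class TestShearModuli:
    def test_inversion_identity(self):
        r_nm, g0 = 250.0, 5.0
        f = np.linspace(10, 1000, 50)
        chi_r = np.full(50, 1.0 / (6 * np.pi * r_nm * 1e-9 * g0))
        resp = ComplexResponse(f, np.zeros(50), chi_real=chi_r,
                               kk_valid_max=1100.0)
        mod = shear_moduli(resp, r_nm)
        assert np.allclose(mod.g_storage, g0)
        assert np.allclose(mod.g_loss, 0.0)

    def test_doubling_radius_halves_moduli(self):
        f = np.linspace(10, 1000, 50)
        resp = ComplexResponse(f, np.full(50, 1e3), chi_real=np.full(50, 2e3),
                               kk_valid_max=1100.0)
        m1 = shear_moduli(resp, 200.0)
        m2 = shear_moduli(resp, 400.0)
        assert np.allclose(m2.g_storage, m1.g_storage / 2)
        assert np.allclose(m2.g_loss, m1.g_loss / 2)

    def test_output_capped_at_kk_valid_max(self):
        f = np.linspace(10, 5000, 200)
        resp = ComplexResponse(f, np.full(200, 1e3),
                               chi_real=np.full(200, 1e3),
                               kk_valid_max=1100.0)
        mod = shear_moduli(resp, 250.0)
        assert mod.frequency.max() <= 1100.0

    def test_missing_real_part_is_a_state_error(self):
        resp = ComplexResponse(np.linspace(1, 10, 5), np.ones(5))
        with pytest.raises(StateError):
            shear_moduli(resp, 250.0)


class TestSubtractTrap:
    def _moduli(self):
        f = np.linspace(10, 1000, 20)
        resp = ComplexResponse(f, np.full(20, 1e3), chi_real=np.full(20, 1e3),
                               kk_valid_max=1100.0)
        return shear_moduli(resp, 250.0)

    def test_zero_subtraction_flips_flag_only(self):
        mod = self._moduli()
        out = subtract_trap(mod, 0.0)
        assert out.trap_corrected
        assert np.array_equal(out.g_storage, mod.g_storage)

    def test_double_subtraction_is_a_state_error(self):
        out = subtract_trap(self._moduli(), 1.0)
        with pytest.raises(StateError):
            subtract_trap(out, 1.0)

    def test_water_calibration_residual_is_small(self):
        """Trap in water: subtracting k/(6 pi r) leaves |G'| << G'_trap."""
        eta, r, T = 1e-3, 0.25e-6, 300.0
        g_trap = 10.6
        k = g_trap * 6 * np.pi * r
        tr, _ = simulate_trapped_viscous_trajectory(k, eta, r, T, 2**19, FS,
                                                    seed=21)
        mod = moduli_from_trajectory(tr, g_trap=g_trap)
        sel = (mod.frequency >= 300) & (mod.frequency <= 1100)
        _, resid = log_band_average(mod.frequency[sel], mod.g_storage[sel],
                                    n_bands=8)
        assert np.abs(resid).max() < 1.0


class TestMsd:
    def test_brownian_slope_near_one(self):
        tr, _ = simulate_brownian_trajectory(2**17, FS, seed=2)
        msd = compute_msd(tr, max_lag_s=0.01)
        assert abs(msd.fitted_alpha - 1.0) < 0.1

    def test_subdiffusive_slope_matches_spectrum_exponent(self):
        tr, _ = simulate_power_law_trajectory(0.5, 2**18, FS, seed=3)
        msd = compute_msd(tr, max_lag_s=0.01)
        assert abs(msd.fitted_alpha - 0.5) < 0.1

    def test_frozen_series_has_zero_msd(self):
        tr = TrajectoryRecord(np.full(2**12, 3.7), FS)
        msd = compute_msd(tr, max_lag_s=0.01)
        assert np.all(msd.msd_nm2 == 0.0)

    def test_cross_estimator_agreement(self):
        """PSD-fit and MSD-fit exponents agree on synthetic power laws."""
        tr, _ = simulate_power_law_trajectory(0.7, 2**18, FS, seed=4)
        a_psd = fit_scaling_exponent(compute_psd(tr, 4096)).alpha
        a_msd = compute_msd(tr, max_lag_s=0.01).fitted_alpha
        assert abs(a_psd - a_msd) < 0.1

    def test_too_short_lag_grid_is_an_error(self):
        tr, _ = simulate_brownian_trajectory(2**12, FS, seed=5)
        with pytest.raises(ParameterError):
            compute_msd(tr, max_lag_s=1e-4)


class TestTrajectoryIO:
    def test_roundtrip_preserves_data_and_metadata(self, tmp_path, rng):
        tr = TrajectoryRecord(rng.standard_normal(256), FS,
                              bead_radius_nm=250.0, temperature_K=310.15,
                              condition="2i", location="periphery")
        p = tmp_path / "traj.tsv"
        save_trajectory(tr, p)
        back = load_trajectory(p)
        assert np.allclose(back.position_nm, tr.position_nm, atol=1e-6)
        assert back.sampling_rate == FS
        assert back.condition == "2i"
        assert back.bead_radius_nm == 250.0
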