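import numpy as np
import pytest

import mrsphase as mp
from mrsphase import fitting as ft
from mrsphase import preprocess as pp
from mrsphase import simulate as sim
from mrsphase.preprocess import CombinedSpectrum

from conftest import single_lorentzian_spectrum


class TestLinearCombinationFit:
    def test_noiseless_single_model_recovered_exactly(self):
        spec, model = single_lorentzian_spectrum(amp=10.0)
        res = ft.fit_linear_combination(spec, [model])
        assert res.amplitudes["peak"] == pytest.approx(10.0, rel=1e-6)
        assert np.abs(res.baseline).max() < 1e-6 * 10.0
        assert res.nuisance["shift_hz"] == pytest.approx(0.0, abs=0.01)

    def test_duplicate_basis_model_rejected(self):
        spec, model = single_lorentzian_spectrum()
        with pytest.raises(ft.SingularBasisError, match="duplicate"):
            ft.fit_linear_combination(spec, [model, model])

    def test_collinear_distinct_names_rejected(self):
        spec, model = single_lorentzian_spectrum()
        import dataclasses

        clone = dataclasses.replace(model, name="peak2")
        with pytest.raises(ft.SingularBasisError, match="collinear"):
            ft.fit_linear_combination(spec, [model, clone])

    def test_two_metabolites_unbiased_and_crlb_consistent(self):
        """Monte-Carlo: amplitude estimates unbiased, empirical SD within
        25% of the Fisher-information prediction."""
        acq = mp.slaser_7t(n_channels=1, n_averages=1, n_points=1024)
        m1 = mp.MetaboliteModel(
            "a", (mp.Resonance(2.0, 1.0, 8.0),), t2_ms=100, proton_count=1
        )
        m2 = mp.MetaboliteModel(
            "b", (mp.Resonance(3.2, 1.0, 8.0),), t2_ms=100, proton_count=1
        )
        rng = np.random.default_rng(42)
        true = {"a": 20.0, "b": 12.0}
        fid0 = true["a"] * m1.unit_fid(acq) + true["b"] * m2.unit_fid(acq)
        sd = 0.5
        amps, crlbs = [], []
        for _ in range(60):
            fid = fid0 + sd * (
                rng.standard_normal(acq.n_points)
                + 1j * rng.standard_normal(acq.n_points)
            )
            res = ft.fit_linear_combination(
                CombinedSpectrum(fid, acq), [m1, m2],
                shift_starts_hz=(0.0,),
            )
            amps.append([res.amplitudes["a"], res.amplitudes["b"]])
            crlbs.append([res.amplitude_sd["a"], res.amplitude_sd["b"]])
        amps = np.array(amps)
        mc_se = amps.std(axis=0) / np.sqrt(len(amps))
        for k, name in enumerate(["a", "b"]):
            assert abs(amps[:, k].mean() - true[name]) < 4 * mc_se[k]
            ratio = amps[:, k].std() / np.mean(crlbs, axis=0)[k]
            assert 0.75 < ratio < 1.25

    def test_residuals_uncorrelated_with_basis(self):
        spec, model = single_lorentzian_spectrum(amp=10.0, noise_sd=0.05, seed=3)
        res = ft.fit_linear_combination(spec, [model])
        col = np.cos(np.linspace(0, 1, len(res.residuals)))  # arbitrary probe
        # the fitted component itself must be orthogonal to the residual
        mask = (spec.ppm >= 0.2) & (spec.ppm <= 4.2)
        basis_col = spec.spectrum.real[mask][::-1]
        r = np.corrcoef(res.residuals, basis_col)[0, 1]
        assert abs(r) < 0.05


class TestLorentzianCRLB:
    def test_fisher_matches_numerical_hessian_oracle(self):
        """CRLB from the Fisher information vs a brute-force Hessian of the
        least-squares objective, on a 3-parameter single-Lorentzian problem."""
        spec, _ = single_lorentzian_spectrum(amp=10.0, shift_ppm=3.0,
                                             linewidth_hz=9.0)
        fit = ft.fit_lorentzian_peak(spec, 3.0)
        acq = spec.acquisition
        ppm = spec.ppm
        mask = np.abs(ppm - 3.0) <= 0.15
        data = spec.spectrum[mask]
        f_hz = (ppm[mask] - mp.core.WATER_PPM) * acq.larmor_frequency_mhz
        sigma = 0.3  # fixed noise scale for both routes

        def chi2(theta):
            model = ft._lorentzian_dft(
                (theta[0], theta[1], theta[2], 0.0), f_hz, acq.n_points,
                acq.dwell_time_s,
            )
            r = data - model
            return float(np.sum(r.real**2 + r.imag**2)) / (2 * sigma**2)

        theta0 = np.array([fit.area, (fit.center_ppm - mp.core.WATER_PPM)
                           * acq.larmor_frequency_mhz, fit.fwhm_hz])
        h = np.array([1e-5 * abs(fit.area), 1e-4, 1e-4])
        hess = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                tpp = theta0.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta0.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta0.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta0.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                hess[i, j] = (chi2(tpp) - chi2(tpm) - chi2(tmp) + chi2(tmm)) / (
                    4 * h[i] * h[j]
                )
        oracle_sd = np.sqrt(np.linalg.inv(hess)[0, 0])

        # Fisher route with the same fixed sigma and phase held at optimum
        def residuals(theta):
            model = ft._lorentzian_dft(
                (theta[0], theta[1], theta[2], 0.0), f_hz, acq.n_points,
                acq.dwell_time_s,
            )
            r = data - model
            return np.r_[r.real, r.imag]

        eps = 1e-7
        jac = np.column_stack([
            (residuals(theta0 + e) - residuals(theta0 - e)) / (2 * eps_i)
            for e, eps_i in (
                (np.array([eps * abs(fit.area), 0, 0]), eps * abs(fit.area)),
                (np.array([0, eps * 100, 0]), eps * 100),
                (np.array([0, 0, eps * 100]), eps * 100),
            )
        ])
        fisher_sd = np.sqrt(np.linalg.inv(jac.T @ jac / sigma**2)[0, 0])
        assert fisher_sd == pytest.approx(oracle_sd, rel=0.01)

    def test_crlb_scales_with_noise(self):
        """Doubling the noise SD doubles the reported CRLB percentage."""
        ratios = []
        for seed in range(15):
            crlb = {}
            for sd in (0.2, 0.4):
                spec, _ = single_lorentzian_spectrum(
                    amp=10.0, shift_ppm=3.0, noise_sd=sd, seed=seed
                )
                crlb[sd] = ft.fit_lorentzian_peak(spec, 3.0).crlb_percent
            ratios.append(crlb[0.4] / crlb[0.2])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)


class TestEditedGaba:
    def _single_line_pair(self, gaba_amp, cr_amp, efficiency, noise_sd=0.0, seed=0):
        acq = mp.mega_slaser_7t(n_channels=1, n_averages=2)
        gaba = mp.MetaboliteModel(
            "GABA", (mp.Resonance(3.01, 1.0, 10.0),), t2_ms=88, proton_count=1,
            edit_co_factor=efficiency,
        )
        cr = mp.MetaboliteModel(
            "tCr", (mp.Resonance(3.03, 1.0, 8.0),), t2_ms=92, proton_count=1
        )
        rng = np.random.default_rng(seed)

        def noisy(fid):
            if not noise_sd:
                return fid
            return fid + noise_sd * (
                rng.standard_normal(acq.n_points)
                + 1j * rng.standard_normal(acq.n_points)
            )

        off = gaba_amp * gaba.unit_fid(acq) + cr_amp * cr.unit_fid(acq)
        diff = efficiency * gaba_amp * gaba.unit_fid(acq)
        return (
            CombinedSpectrum(noisy(diff), acq),
            CombinedSpectrum(noisy(off), acq),
        )

    def test_noiseless_efficiency_correction_exact(self):
        diff, off = self._single_line_pair(10.0, 30.0, efficiency=0.5)
        res = ft.fit_edited_gaba(
            diff, off, editing_efficiency=0.5,
            gaba_reference_fraction=1.0, cr_reference_fraction=1.0,
        )
        assert res.gaba_area == pytest.approx(10.0, rel=1e-6)

    def test_full_model_mega_quantification(self, subject, small_mega, basis):
        """End to end on the default multiplets: corrected GABA area inverts
        the forward model within a percent (line-overlap limited)."""
        sess = sim.synthesize_session(
            subject, "Baseline", small_mega, mp.DistortionConfig.none(), seed=3,
            basis=basis,
        )
        res = pp.preprocess_session(sess)
        eg = ft.fit_edited_gaba(res.difference_spectrum, res.off_spectrum)
        expected = sim.metabolite_signal_amplitude(
            subject.true_concentrations["GABA"]["Baseline"], basis["GABA"],
            subject.tissue_fractions, small_mega.echo_time_ms,
        )
        assert eg.gaba_area == pytest.approx(expected, rel=0.01)

    def test_zero_gaba_statistically_null(self):
        """With no GABA, the corrected area is consistent with zero."""
        violations = 0
        for seed in range(40):
            diff, off = self._single_line_pair(
                0.0, 30.0, efficiency=0.5, noise_sd=0.3, seed=seed
            )
            res = ft.fit_edited_gaba(
                diff, off, editing_efficiency=0.5,
                gaba_reference_fraction=1.0, cr_reference_fraction=1.0,
            )
            z = res.gaba_fit.area / res.gaba_fit.area_sd
            if abs(z) >= 3:
                violations += 1
        assert violations <= 2

    def test_negative_area_flagged(self):
        diff, off = self._single_line_pair(10.0, 30.0, efficiency=0.5)
        neg = CombinedSpectrum(-diff.fid, diff.acquisition)
        res = ft.fit_edited_gaba(
            neg, off, editing_efficiency=0.5,
            gaba_reference_fraction=1.0, cr_reference_fraction=1.0,
        )
        assert "negative_area" in res.gaba_fit.flags
        assert res.gaba_area < 0


class TestQualityMetrics:
    def _flat_spectrum_with(self, values_by_ppm, acq=None):
        from mrsphase.core import fid_from_spectrum

        acq = acq or mp.slaser_7t(n_channels=1, n_averages=1)
        ppm = acq.ppm_axis()
        spec = np.zeros(acq.n_points, dtype=complex)
        for target, value in values_by_ppm.items():
            spec[np.argmin(np.abs(ppm - target))] = value
        return CombinedSpectrum(fid_from_spectrum(spec), acq)

    def test_snr_definition_direct(self):
        """max - baseline = 100, residual RMS = 2  ->  SNR = 25."""
        spec = self._flat_spectrum_with({2.0: 100.0})
        fit = ft.FitResult(
            amplitudes={}, amplitude_sd={}, crlb_percent={}, nuisance={},
            baseline=np.zeros(50), residuals=np.full(50, 2.0),
            window_ppm=np.linspace(0.2, 4.2, 50), noise_sd=1.0,
        )
        assert ft.snr_lcmodel_style(spec, fit) == pytest.approx(25.0)

    def test_snr_scale_invariant(self):
        spec = self._flat_spectrum_with({2.0: 100.0})
        fit = ft.FitResult(
            amplitudes={}, amplitude_sd={}, crlb_percent={}, nuisance={},
            baseline=np.full(50, 5.0), residuals=np.full(50, 2.0),
            window_ppm=np.linspace(0.2, 4.2, 50), noise_sd=1.0,
        )
        base = ft.snr_lcmodel_style(spec, fit)
        c = 7.3
        scaled_spec = CombinedSpectrum(c * spec.fid, spec.acquisition)
        scaled_fit = ft.FitResult(
            amplitudes={}, amplitude_sd={}, crlb_percent={}, nuisance={},
            baseline=c * fit.baseline, residuals=c * fit.residuals,
            window_ppm=fit.window_ppm, noise_sd=c,
        )
        assert ft.snr_lcmodel_style(scaled_spec, scaled_fit) == pytest.approx(base)

    def test_zero_residual_warns_infinite(self):
        spec = self._flat_spectrum_with({2.0: 100.0})
        fit = ft.FitResult(
            amplitudes={}, amplitude_sd={}, crlb_percent={}, nuisance={},
            baseline=np.zeros(50), residuals=np.zeros(50),
            window_ppm=np.linspace(0.2, 4.2, 50), noise_sd=1.0,
        )
        with pytest.warns(UserWarning, match="noiseless"):
            assert np.isinf(ft.snr_lcmodel_style(spec, fit))

    def test_creatine_snr_direct_ratio(self):
        acq = mp.slaser_7t(n_channels=1, n_averages=1)
        ppm = acq.ppm_axis()
        spec_vals = np.zeros(acq.n_points, dtype=complex)
        region = (ppm >= 8) & (ppm <= 10)
        spec_vals[region] = 0.25 * (-1.0) ** np.arange(region.sum())
        from mrsphase.core import fid_from_spectrum

        spec = CombinedSpectrum(fid_from_spectrum(spec_vals), acq)
        assert ft.snr_creatine(spec, cr_area=50.0) == pytest.approx(200.0, rel=1e-3)
        # adding signal below 8 ppm leaves the denominator unchanged
        spec_vals2 = spec_vals.copy()
        spec_vals2[np.argmin(np.abs(ppm - 3.0))] = 500.0
        spec2 = CombinedSpectrum(fid_from_spectrum(spec_vals2), acq)
        assert ft.snr_creatine(spec2, cr_area=50.0) == pytest.approx(200.0, rel=1e-3)

    def test_fwhm_closed_form_t2star(self):
        """A pure Lorentzian decay with T2* = 100 ms has FWHM 1/(pi 0.1 s)."""
        acq = mp.slaser_7t(n_channels=1, n_averages=1)
        t = acq.time_axis_s()
        f_hz = (2.01 - mp.core.WATER_PPM) * acq.larmor_frequency_mhz
        fid = np.exp((2j * np.pi * f_hz) * t) * np.exp(-t / 0.1)
        spec = CombinedSpectrum(fid, acq)
        fwhm_ppm, fwhm_hz = ft.fwhm_naa(spec)
        assert fwhm_hz == pytest.approx(1 / (np.pi * 0.1), rel=0.15)
        assert fwhm_hz == fwhm_ppm * acq.larmor_frequency_mhz  # exact identity

    def test_fwhm_doubles_with_linewidth(self):
        acq = mp.slaser_7t(n_channels=1, n_averages=1)
        widths = {}
        for lw in (8.0, 16.0):
            spec, _ = single_lorentzian_spectrum(
                shift_ppm=2.01, linewidth_hz=lw, acquisition=acq
            )
            widths[lw] = ft.fwhm_naa(spec)[1]
        bin_hz = acq.spectral_width_hz / acq.n_points
        assert abs(widths[16.0] - 2 * widths[8.0]) < 2 * bin_hz

    def test_missing_naa_peak_raises(self):
        spec = self._flat_spectrum_with({3.5: 100.0})
        with pytest.raises(ValueError, match="NAA"):
            ft.fwhm_naa(spec)
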