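"""Signal/noise building blocks and the three CNR modalities."""

import numpy as np
import pytest

from plasmonsense.sensing import (DetectionConfig, PhotothermalParams,
                                  apply_qe, cnr, cnr_fixed_wavelength,
                                  cnr_photothermal, cnr_spectral,
                                  estimate_eta_monte_carlo, fit_noise,
                                  fom_intensity, fom_spectral,
                                  registered_signal, shot_noise, snr,
                                  total_noise)
from plasmonsense.spectra import Spectrum, binding_response


def lorentz(lam, lam0, gamma, cmax, base=0.0):
    hw2 = (gamma / 2.0) ** 2
    return base + cmax * hw2 / ((lam - lam0) ** 2 + hw2)


GRID = np.linspace(750.0, 850.0, 15)


def make_response(shift=0.4, amp=0.0, widen=0.0, gamma=40.0, cmax=5e-3):
    v0 = lorentz(GRID, 800.0, gamma, cmax)
    v1 = lorentz(GRID, 800.0 + shift, gamma * (1 + widen), cmax * (1 + amp))
    return binding_response(Spectrum(GRID, v0), Spectrum(GRID, v1))


class TestElementaryOps:
    def test_registered_signal_arithmetic(self):
        """Phi*bw = 1e18 /m^2/s, C = 1e-14 m^2, dt = 1e-2 s -> 100 counts."""
        lam = 800.0
        cfg = DetectionConfig(intensity_W_m2=1.0, bandwidth_nm=1.0,
                              dt_s=1e-2)
        phi = cfg.photon_flux(lam)
        c_um2 = 1e-14 / 1e-12  # 1e-14 m^2 in um^2
        s = registered_signal(cfg, c_um2, lam)
        assert s == pytest.approx(phi * 1e-14 * 1e-2)
        # and the printed example, with Phi*bw forced to 1e18:
        scale = 1e18 / phi
        assert s * scale == pytest.approx(100.0)

    def test_zero_cross_section_zero_counts(self):
        assert registered_signal(DetectionConfig(), 0.0, 800.0) == 0.0

    def test_signal_linear_in_dt(self):
        c1 = DetectionConfig(dt_s=1e-2)
        c2 = DetectionConfig(dt_s=2e-2)
        s1 = registered_signal(c1, 1e-3, 800.0)
        s2 = registered_signal(c2, 1e-3, 800.0)
        assert s2 == pytest.approx(2 * s1)

    def test_shot_noise(self):
        assert shot_noise(0.0) == 0.0
        assert shot_noise(100.0) == 10.0

    def test_poisson_sd_is_sqrt_mean(self):
        rng = np.random.default_rng(11)
        draws = rng.poisson(400.0, size=100_000)
        se = 20.0 / np.sqrt(2 * (draws.size - 1))  # SE of the SD
        assert draws.std(ddof=1) == pytest.approx(20.0, abs=3 * se + 0.15)

    def test_total_noise_pythagoras(self):
        cfg = DetectionConfig(sigma_sys_counts=3.0, read_noise_counts=4.0)
        nm = total_noise(cfg, 0.0)
        assert nm.total == pytest.approx(5.0)

    def test_detector_noise_dark_current(self):
        cfg = DetectionConfig(dark_current_cps=100.0, dt_s=1.0,
                              read_noise_counts=10.0)
        assert total_noise(cfg, 0.0).sigma_det == pytest.approx(
            np.sqrt(200.0))

    def test_snr_is_sqrt_signal(self):
        cfg = DetectionConfig()
        s = registered_signal(cfg, 1e-3, 800.0)
        assert snr(cfg, 1e-3, 800.0) == pytest.approx(np.sqrt(s))
        cfg2 = DetectionConfig(dt_s=cfg.dt_s * 2)
        assert snr(cfg2, 1e-3, 800.0) / snr(cfg, 1e-3, 800.0) == \
            pytest.approx(np.sqrt(2))

    def test_cnr_arithmetic(self):
        assert cnr(5.0, 5.0, 1.0, 1.0) == 0.0
        assert cnr(0.0, 10.0, np.sqrt(2), np.sqrt(2)) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            cnr(1.0, 2.0, 0.0, 0.0)


class TestFoms:
    def test_fom_spectral(self):
        r = make_response(shift=0.39, gamma=39.0)
        assert fom_spectral(r) == pytest.approx(0.01, rel=0.05)
        assert fom_spectral(make_response(shift=0.0)) == pytest.approx(
            0.0, abs=1e-6)

    def test_fom_intensity_uniform_amplitude(self):
        r = make_response(shift=0.0, amp=0.01)
        assert fom_intensity(r) == pytest.approx(0.01, rel=0.05)

    def test_fom_intensity_matches_brute_force(self):
        r = make_response(shift=1.0)
        dense = np.arange(GRID[0], GRID[-1], 0.01)
        rel = np.abs(lorentz(dense, 801.0, 40.0, 5e-3)
                     - lorentz(dense, 800.0, 40.0, 5e-3)) / \
            lorentz(dense, 800.0, 40.0, 5e-3)
        assert fom_intensity(r) == pytest.approx(rel.max(), rel=0.02)


class TestFitNoise:
    def test_fit_noise_arithmetic(self):
        r = make_response()
        fit = r.fit_without
        cfg = DetectionConfig()
        s = snr(cfg, float(fit(fit.lambda_res_nm)), fit.lambda_res_nm)
        assert fit_noise(fit, cfg, eta=0.21) == pytest.approx(
            0.21 * fit.gamma_nm / s)

    def test_fit_noise_scaling_with_flux(self):
        r = make_response()
        s1 = fit_noise(r.fit_without, DetectionConfig(intensity_W_m2=1e7))
        s2 = fit_noise(r.fit_without, DetectionConfig(intensity_W_m2=4e7))
        assert s2 == pytest.approx(s1 / 2.0)


class TestEtaMonteCarlo:
    def test_eta_near_published_value(self):
        eta = estimate_eta_monte_carlo(n_trials=500, seed=0)
        assert eta == pytest.approx(0.21, abs=0.03)

    def test_eta_independent_of_gamma(self):
        e1 = estimate_eta_monte_carlo(gamma_nm=30.0, n_trials=400, seed=1)
        e2 = estimate_eta_monte_carlo(gamma_nm=60.0, n_trials=400, seed=2)
        assert abs(e1 - e2) < 0.04

    def test_eta_independent_of_snr(self):
        e1 = estimate_eta_monte_carlo(snr_peak=30.0, n_trials=400, seed=3)
        e2 = estimate_eta_monte_carlo(snr_peak=300.0, n_trials=400, seed=4)
        assert abs(e1 - e2) < 0.04

    def test_reproducible(self):
        assert estimate_eta_monte_carlo(n_trials=200, seed=7) == \
            estimate_eta_monte_carlo(n_trials=200, seed=7)


class TestModalities:
    def test_spectral_zero_shift(self):
        res = cnr_spectral(make_response(shift=0.0), DetectionConfig())
        assert res.cnr == pytest.approx(0.0, abs=1e-6)

    def test_spectral_full_vs_simplified(self):
        """Both Eq-forms agree when the bound state barely changes."""
        res = cnr_spectral(make_response(shift=0.2, amp=0.005,
                                         widen=0.005), DetectionConfig())
        assert res.cnr == pytest.approx(res.cnr_simplified, rel=0.02)

    def test_spectral_proportional_to_fom_times_snr(self):
        """CNR / (FOM * SNR) is constant over an intensity scan."""
        r = make_response()
        ratios = []
        for i0 in (1e6, 1e7, 1e8):
            cfg = DetectionConfig(intensity_W_m2=i0)
            res = cnr_spectral(r, cfg)
            fit = r.fit_without
            s = snr(cfg, float(fit(fit.lambda_res_nm)), fit.lambda_res_nm)
            ratios.append(res.cnr / (res.fom * s))
        assert np.ptp(ratios) / np.mean(ratios) < 1e-9

    def test_fixed_wavelength_scalings(self):
        r = make_response()
        res1 = cnr_fixed_wavelength(r, DetectionConfig(intensity_W_m2=1e7))
        res4 = cnr_fixed_wavelength(r, DetectionConfig(intensity_W_m2=4e7))
        assert res4.cnr == pytest.approx(2 * res1.cnr, rel=1e-9)
        assert cnr_fixed_wavelength(make_response(shift=0.0),
                                    DetectionConfig()).cnr == \
            pytest.approx(0.0, abs=1e-9)

    def test_fixed_wavelength_vs_simplified(self):
        res = cnr_fixed_wavelength(make_response(shift=0.2, amp=0.002),
                                   DetectionConfig())
        assert res.cnr == pytest.approx(res.cnr_simplified, rel=0.02)

    def test_photothermal_linear_in_heating(self):
        r = make_response()
        cfg = DetectionConfig()
        p1 = PhotothermalParams(i_heat_W_m2=1.0)
        p2 = PhotothermalParams(i_heat_W_m2=2.0)
        c1 = cnr_photothermal(r, p1, cfg).cnr
        c2 = cnr_photothermal(r, p2, cfg).cnr
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_photothermal_probe_scaling(self):
        r = make_response()
        cfg = DetectionConfig()
        c1 = cnr_photothermal(r, PhotothermalParams(phi_probe=1e24), cfg).cnr
        c4 = cnr_photothermal(r, PhotothermalParams(phi_probe=4e24), cfg).cnr
        assert c4 == pytest.approx(2 * c1, rel=1e-12)
        assert cnr_photothermal(make_response(shift=0.0),
                                PhotothermalParams(), cfg).cnr == \
            pytest.approx(0.0, abs=1e-9)

    def test_cnr_sqrt_flux_time_scaling(self):
        """Shot-noise limit: CNR ~ sqrt(Phi dt) over two decades."""
        r = make_response()
        i0s = np.logspace(6, 8, 5)
        for fn in (lambda c: cnr_spectral(r, c).cnr,
                   lambda c: cnr_fixed_wavelength(r, c).cnr):
            vals = [fn(DetectionConfig(intensity_W_m2=i)) for i in i0s]
            slope = np.polyfit(np.log(i0s), np.log(vals), 1)[0]
            assert slope == pytest.approx(0.5, abs=0.01)

    def test_apply_qe(self):
        res = cnr_spectral(make_response(), DetectionConfig())
        assert apply_qe(res, 1.0).cnr == res.cnr
        assert apply_qe(res, 0.25).cnr == pytest.approx(res.cnr / 2)
        with pytest.raises(ValueError):
            apply_qe(res, 0.0)
        curve = lambda lam: 0.49  # noqa: E731
        assert apply_qe(res, curve).cnr == pytest.approx(0.7 * res.cnr)


class TestMonteCarloPipeline:
    def test_empirical_cnr_matches_analytic(self):
        """Poisson count pairs at lambda_max reproduce the analytic CNR."""
        rng = np.random.default_rng(5)
        s1, s2 = 10_000.0, 10_400.0
        analytic = cnr(s1, s2, np.sqrt(s1), np.sqrt(s2))
        n = 10_000
        d = rng.poisson(s2, n) - rng.poisson(s1, n)
        empirical = abs(d.mean()) / np.sqrt(
            rng.poisson(s1, n).var() + rng.poisson(s2, n).var())
        assert empirical == pytest.approx(analytic, rel=0.05)
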