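"""Signal, noise, SNR and contrast-to-noise ratios for the three modalities.

The contrast-to-noise ratio CNR = |s2 - s1| / sqrt(sigma1^2 + sigma2^2)
relates the step in a time trace caused by a single binding event to the
combined root-mean-square noise of the two states.  Three modalities are
implemented:

* spectral: the signal is the fitted resonance position; its noise is the
  peak-fit uncertainty sigma_fit = eta * Gamma / SNR (eta = 0.21);
* fixed-wavelength scattering: the signal is the photon count at
  lambda_max on the long-wavelength flank; shot-noise limited;
* fixed-wavelength photothermal: the signal is the probe-beam scattering
  off the thermal lens, linear in Delta C_abs and in the heating intensity,
  with noise set by the probe beam alone.

All counts assume the shot-noise-limited regime unless detector noise
parameters are set explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import BindingResponse, LorentzianFit, Spectrum, fit_lorentzian

__all__ = [
    "DetectionConfig",
    "NoiseModel",
    "FitNoiseParams",
    "PhotothermalParams",
    "SensingResult",
    "registered_signal",
    "shot_noise",
    "total_noise",
    "snr",
    "fom_spectral",
    "fom_intensity",
    "cnr",
    "fit_noise",
    "estimate_eta_monte_carlo",
    "cnr_spectral",
    "cnr_fixed_wavelength",
    "cnr_photothermal",
    "apply_qe",
]

H_C_J_M = 1.98644586e-25  # Planck constant times speed of light, J*m
ETA_DEFAULT = 0.21  # peak-fit noise proportionality factor
UM2_TO_M2 = 1e-12


@dataclass(frozen=True)
class DetectionConfig:
    """Illumination and detector parameters.

    ``intensity_W_m2`` is the spectral illumination intensity per nm of
    bandwidth; the photon flux density Phi = I0 / (h nu) follows from it at
    the sensing wavelength.  Defaults describe an ideal setup
    (A_SYS = A_DET = 1, no detector noise) in the shot-noise limit.
    """

    intensity_W_m2: float = 1e7
    bandwidth_nm: float = 1.0
    dt_s: float = 1e-2
    a_sys: float = 1.0
    a_det: float = 1.0  # scalar QE; wavelength curves enter via apply_qe
    detector_area_m2: float = 1e-12
    dark_current_cps: float = 0.0
    read_noise_counts: float = 0.0
    sigma_sys_counts: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_W_m2 <= 0 or self.bandwidth_nm <= 0 or \
                self.dt_s <= 0:
            raise ValueError("intensity, bandwidth and dt must be positive")
        if not (0 < self.a_sys <= 1 and 0 < self.a_det <= 1):
            raise ValueError("A_SYS and A_DET must lie in (0, 1]")

    def photon_flux(self, wavelength_nm: float) -> float:
        """Phi: photons / s / m^2 per nm of bandwidth at this wavelength."""
        e_photon = H_C_J_M / (wavelength_nm * 1e-9)
        return self.intensity_W_m2 / e_photon

    def scaled(self, intensity_W_m2: float) -> "DetectionConfig":
        return replace(self, intensity_W_m2=intensity_W_m2)


@dataclass(frozen=True)
class NoiseModel:
    """Noise budget in counts; total is the quadrature sum."""

    sigma_sys: float
    sigma_det: float
    sigma_shot: float

    @property
    def total(self) -> float:
        return float(np.sqrt(self.sigma_sys**2 + self.sigma_det**2
                             + self.sigma_shot**2))


@dataclass(frozen=True)
class FitNoiseParams:
    eta: float = ETA_DEFAULT

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass(frozen=True)
class PhotothermalParams:
    """Opaque photothermal constants; only relative CNR maps are meaningful.

    ``c_th_um2_per_W``: scattering cross section of the thermal lens per
    watt of dissipated power.  ``i_heat_W_m2``: heating-beam intensity.
    ``phi_probe``: probe photon flux density (photons/s/m^2/nm).
    """

    c_th_um2_per_W: float = 1.0
    i_heat_W_m2: float = 1.0
    phi_probe: float = 1e25

    def __post_init__(self) -> None:
        if min(self.c_th_um2_per_W, self.i_heat_W_m2, self.phi_probe) <= 0:
            raise ValueError("photothermal parameters must be positive")


@dataclass(frozen=True)
class SensingResult:
    modality: str
    sensing_wavelength_nm: float
    signal_1: float
    signal_2: float
    sigma_1: float
    sigma_2: float
    cnr: float
    fom: float
    cnr_simplified: float | None = None

    def __post_init__(self) -> None:
        if self.cnr < 0:
            raise ValueError("CNR must be >= 0")


# ---------------------------------------------------------------------------
# elementary signal/noise operations


def registered_signal(config: DetectionConfig, a_np_um2: float,
                      wavelength_nm: float) -> float:
    """Registered photon counts s = Phi * bw * A_NP * A_SYS * A_DET * dt."""
    if a_np_um2 < 0:
        raise ValueError("scattering factor A_NP must be >= 0")
    phi = config.photon_flux(wavelength_nm)
    return (phi * config.bandwidth_nm * a_np_um2 * UM2_TO_M2
            * config.a_sys * config.a_det * config.dt_s)


def shot_noise(s_counts: float) -> float:
    """Poisson shot noise sqrt(s)."""
    if s_counts < 0:
        raise ValueError("counts must be >= 0")
    return float(np.sqrt(s_counts))


def total_noise(config: DetectionConfig, s_counts: float) -> NoiseModel:
    """System + detector + shot noise; sigma_det = sqrt(I_D dt + sigma_R^2)."""
    sigma_det = np.sqrt(config.dark_current_cps * config.dt_s
                        + config.read_noise_counts**2)
    return NoiseModel(
        sigma_sys=config.sigma_sys_counts,
        sigma_det=float(sigma_det),
        sigma_shot=shot_noise(s_counts),
    )


def snr(config: DetectionConfig, a_np_um2: float,
        wavelength_nm: float) -> float:
    """Shot-noise-limited SNR = sqrt(registered counts)."""
    return float(np.sqrt(registered_signal(config, a_np_um2, wavelength_nm)))


def cnr(signal_1: float, signal_2: float, sigma_1: float,
        sigma_2: float) -> float:
    """CNR = |s2 - s1| / sqrt(sigma1^2 + sigma2^2)."""
    if sigma_1 < 0 or sigma_2 < 0:
        raise ValueError("noise terms must be >= 0")
    denom = np.hypot(sigma_1, sigma_2)
    if denom == 0:
        raise ValueError("CNR undefined for zero noise in both states")
    return float(abs(signal_2 - signal_1) / denom)


# ---------------------------------------------------------------------------
# noise-independent figures of merit


def fom_spectral(response: BindingResponse) -> float:
    """FOM_lambda = single-molecule resonance shift over bare linewidth."""
    return float(abs(response.delta_lambda_nm)
                 / response.fit_without.gamma_nm)


def fom_intensity(response: BindingResponse, kind: str = "scat") -> float:
    """Maximum relative intensity change max_lam |dC(lam)| / C(lam, bare).

    ``kind`` is informational; the response object carries the curves of
    whichever cross section it was built from.
    """
    del kind
    lam = response.dense_wavelengths_nm
    base = response.C_without(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(response.delta_C) / base
    rel[~np.isfinite(rel)] = 0.0
    return float(rel.max())


# ---------------------------------------------------------------------------
# spectral sensing


def fit_noise(fit: LorentzianFit, config: DetectionConfig,
              eta: float = ETA_DEFAULT) -> float:
    """Peak-fit position noise sigma_fit = eta * Gamma / SNR (nm).

    SNR is the shot-noise-limited single-particle SNR at the fitted peak.
    """
    c_peak = fit(fit.lambda_res_nm)
    s = snr(config, float(c_peak), fit.lambda_res_nm)
    if s == 0:
        raise ValueError("zero SNR: no registered signal at the peak")
    return float(eta * fit.gamma_nm / s)


def estimate_eta_monte_carlo(gamma_nm: float = 40.0, snr_peak: float = 50.0,
                             n_trials: int = 500, seed: int = 0,
                             n_points: int = 21, span_gammas: float = 1.2,
                             lambda_res_nm: float = 800.0) -> float:
    """Monte-Carlo estimate of the peak-fit noise factor eta.

    Simulates Poisson-noised Lorentzian count spectra (peak mean snr_peak^2
    so that the peak SNR equals ``snr_peak``), fits each with the Lorentzian
    model, and returns SD(lambda_res) * SNR / Gamma.  Deterministic for a
    fixed seed; raises if more than 5% of the fits fail.
    """
    if n_trials < 100:
        raise ValueError("need at least 100 trials")
    rng = np.random.default_rng(seed)
    lam = np.linspace(lambda_res_nm - span_gammas * gamma_nm,
                      lambda_res_nm + span_gammas * gamma_nm, n_points)
    peak_counts = snr_peak**2
    hw2 = (gamma_nm / 2.0) ** 2
    mean = peak_counts * hw2 / ((lam - lambda_res_nm) ** 2 + hw2)

    centers = []
    failures = 0
    for _ in range(n_trials):
        counts = rng.poisson(mean).astype(float)
        try:
            fit = fit_lorentzian(Spectrum(lam, counts, kind="counts"))
        except ValueError:
            failures += 1
            continue
        centers.append(fit.lambda_res_nm)
    if failures > 0.05 * n_trials:
        raise RuntimeError(f"{failures}/{n_trials} Lorentzian fits failed")
    sd = float(np.std(centers, ddof=1))
    return sd * snr_peak / gamma_nm


def cnr_spectral(response: BindingResponse, config: DetectionConfig,
                 eta: float = ETA_DEFAULT) -> SensingResult:
    """Spectral-sensing CNR: resonance shift over combined peak-fit noise.

    Uses state-specific Gamma and C_scat(lambda_res) in each sigma_fit.
    ``cnr_simplified`` reports the one-state approximation
    delta_lambda * SNR1 / (eta * Gamma1 * sqrt(2)), valid when the bound
    state barely changes Gamma and C_max.
    """
    sig1 = fit_noise(response.fit_without, config, eta)
    sig2 = fit_noise(response.fit_with, config, eta)
    value = cnr(response.fit_without.lambda_res_nm,
                response.fit_with.lambda_res_nm, sig1, sig2)
    fit0 = response.fit_without
    snr1 = snr(config, float(fit0(fit0.lambda_res_nm)), fit0.lambda_res_nm)
    simplified = abs(response.delta_lambda_nm) * snr1 / (
        eta * fit0.gamma_nm * np.sqrt(2.0))
    return SensingResult(
        modality="spectral",
        sensing_wavelength_nm=fit0.lambda_res_nm,
        signal_1=fit0.lambda_res_nm,
        signal_2=response.fit_with.lambda_res_nm,
        sigma_1=sig1,
        sigma_2=sig2,
        cnr=value,
        fom=fom_spectral(response),
        cnr_simplified=float(simplified),
    )


# ---------------------------------------------------------------------------
# fixed-wavelength scattering


def cnr_fixed_wavelength(response: BindingResponse,
                         config: DetectionConfig) -> SensingResult:
    """Fixed-wavelength scattering CNR at lambda_max, shot-noise limited.

    s_i = Phi bw C_scat,i(lambda_max) dt; sigma_i = sqrt(s_i), so
    CNR_I = |dC| sqrt(Phi bw dt) / sqrt(C1 + C2).
    """
    lam = response.lambda_max_nm
    c1 = float(response.C_without(lam))
    c2 = float(response.C_with(lam))
    s1 = registered_signal(config, c1, lam)
    s2 = registered_signal(config, c2, lam)
    sig1, sig2 = shot_noise(s1), shot_noise(s2)
    value = cnr(s1, s2, sig1, sig2) if (sig1 or sig2) else 0.0
    fom = fom_intensity(response)
    # one-state simplification (noise of both states approximated by the
    # bare state): |dC|/C1 * SNR1 / sqrt(2), evaluated at lambda_max
    simplified = (abs(c2 - c1) / c1) * np.sqrt(max(s1, 0.0)) / np.sqrt(2.0) \
        if (c1 > 0 and s1) else 0.0
    return SensingResult(
        modality="fixed_wavelength",
        sensing_wavelength_nm=lam,
        signal_1=s1,
        signal_2=s2,
        sigma_1=sig1,
        sigma_2=sig2,
        cnr=value,
        fom=fom,
        cnr_simplified=float(simplified),
    )


# ---------------------------------------------------------------------------
# fixed-wavelength photothermal


def cnr_photothermal(response_abs: BindingResponse,
                     params: PhotothermalParams,
                     config: DetectionConfig) -> SensingResult:
    """Photothermal CNR, linear in Delta C_abs and the heating intensity.

    The heating (pump) beam sits at lambda_max of the absorption difference
    spectrum; the probe beam alone sets the noise, so the CNR grows without
    bound with I_heat in this idealized model.
    """
    lam = response_abs.lambda_max_nm
    c1 = float(response_abs.C_without(lam))
    c2 = float(response_abs.C_with(lam))
    pref = params.phi_probe * config.bandwidth_nm * config.dt_s
    s1 = pref * params.c_th_um2_per_W * UM2_TO_M2 * c1 * UM2_TO_M2 \
        * params.i_heat_W_m2
    s2 = pref * params.c_th_um2_per_W * UM2_TO_M2 * c2 * UM2_TO_M2 \
        * params.i_heat_W_m2
    sigma = float(np.sqrt(params.phi_probe * config.bandwidth_nm
                          * config.detector_area_m2 * config.dt_s))
    value = float(abs(s2 - s1) / sigma)
    return SensingResult(
        modality="photothermal",
        sensing_wavelength_nm=lam,
        signal_1=s1,
        signal_2=s2,
        sigma_1=sigma,
        sigma_2=0.0,
        cnr=value,
        fom=fom_intensity(response_abs, kind="abs"),
    )


def apply_qe(result: SensingResult, qe) -> SensingResult:
    """Rescale a CNR for detector quantum efficiency: CNR *= sqrt(QE(lam)).

    ``qe`` may be a scalar or a callable of wavelength (nm).
    """
    q = qe(result.sensing_wavelength_nm) if callable(qe) else float(qe)
    if not 0 < q <= 1:
        raise ValueError("QE must lie in (0, 1] at the sensing wavelength")
    root = float(np.sqrt(q))
    return replace(
        result,
        cnr=result.cnr * root,
        cnr_simplified=(None if result.cnr_simplified is None
                        else result.cnr_simplified * root),
    )
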