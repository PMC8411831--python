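"""Lorentzian resonance fitting and two-state binding observables.

The longitudinal plasmon band is summarized by fitting
``L(lam) = baseline + C_max * (G/2)^2 / ((lam - lam_res)^2 + (G/2)^2)``
to the computed (or measured) cross sections near the peak.  Binding of a
single molecule shifts, broadens and slightly amplifies the resonance; the
signed difference of the two fitted curves on a dense wavelength grid
yields the fixed-wavelength sensing observables (lambda_max, delta C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Spectrum",
    "LorentzianFit",
    "BindingResponse",
    "fit_lorentzian",
    "binding_response",
]

DENSE_GRID_STEP_NM = 0.1  # below any resonance-shift scale of interest


@dataclass(frozen=True)
class Spectrum:
    """Sampled spectrum: cross sections (um^2) or photon counts."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "C_scat"  # C_scat | C_abs | counts

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, float)
        v = np.asarray(self.values, float)
        if w.size < 5:
            raise ValueError("spectrum needs at least 5 points")
        if not (np.diff(w) > 0).all():
            raise ValueError("wavelengths must be ascending")
        if (v < 0).any():
            raise ValueError("spectrum values must be >= 0")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class LorentzianFit:
    """Fitted resonance descriptors: peak position, FWHM, height, baseline."""

    lambda_res_nm: float
    gamma_nm: float  # full width at half maximum
    peak_value: float  # C_max above baseline
    baseline: float
    covariance: np.ndarray
    residual_norm: float

    def __call__(self, lam) -> np.ndarray:
        return _lorentz(np.asarray(lam, float), self.lambda_res_nm,
                        self.gamma_nm, self.peak_value, self.baseline)


def _lorentz(lam, lam0, gamma, cmax, base):
    hw2 = (gamma / 2.0) ** 2
    return base + cmax * hw2 / ((lam - lam0) ** 2 + hw2)


def fit_lorentzian(spectrum: Spectrum, fix_baseline: bool = False,
                   ) -> LorentzianFit:
    """Least-squares Lorentzian fit, initialized from the discrete peak.

    The start values come from the discrete maximum and the half-maximum
    crossings; a spectrum without an interior maximum (monotone) raises.
    ``fix_baseline`` pins the additive baseline to zero.
    """
    lam = spectrum.wavelengths_nm
    val = spectrum.values
    ipk = int(np.argmax(val))
    if ipk in (0, len(val) - 1):
        raise ValueError("no interior maximum; cannot fit a resonance peak")
    vmin, vpk = float(val.min()), float(val[ipk])
    if vpk - vmin <= 0:
        raise ValueError("flat spectrum; cannot fit a resonance peak")

    half = vmin + 0.5 * (vpk - vmin)
    above = val >= half
    gamma0 = max((lam[above][-1] - lam[above][0]),
                 2.0 * float(np.diff(lam).mean()))

    # fit in normalized coordinates (wavelength centered, values scaled to
    # the peak) so all parameters are O(1) for the optimizer
    lam_c = float(lam[ipk])
    span = float(lam[-1] - lam[0])
    x = (lam - lam_c) / span
    v = val / vpk
    p0 = [0.0, gamma0 / span, (vpk - vmin) / vpk, vmin / vpk]
    lo = [(lam[0] - lam_c) / span, 1e-9, 0.0, -np.inf]
    hi = [(lam[-1] - lam_c) / span, np.inf, np.inf, np.inf]

    def model_free(t, lam0, gamma, cmax, base):
        return _lorentz(t, lam0, gamma, cmax, base)

    def model_fixed(t, lam0, gamma, cmax):
        return _lorentz(t, lam0, gamma, cmax, 0.0)

    try:
        if fix_baseline:
            popt, pcov = curve_fit(model_fixed, x, v, p0=p0[:3],
                                   bounds=(lo[:3], hi[:3]), maxfev=20000)
            popt = np.append(popt, 0.0)
            pcov4 = np.zeros((4, 4))
            pcov4[:3, :3] = pcov
            pcov = pcov4
        else:
            popt, pcov = curve_fit(model_free, x, v, p0=p0,
                                   bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"Lorentzian fit did not converge: {exc}") from exc

    # undo the normalization (scale wavelengths by span, values by vpk)
    scale = np.array([span, span, vpk, vpk])
    popt = popt * scale
    popt[0] += lam_c
    pcov = pcov * np.outer(scale, scale)

    resid = val - _lorentz(lam, *popt)
    return LorentzianFit(
        lambda_res_nm=float(popt[0]),
        gamma_nm=float(popt[1]),
        peak_value=float(popt[2]),
        baseline=float(popt[3]),
        covariance=pcov,
        residual_norm=float(np.linalg.norm(resid)),
    )


@dataclass(frozen=True)
class BindingResponse:
    """Two-state (bare / with molecule) resonance comparison.

    ``delta_lambda_nm = lambda_res(with) - lambda_res(without)``;
    ``lambda_max_nm`` is the wavelength of largest |delta C| restricted to
    the long-wavelength side of the bare resonance, where the binding-
    induced intensity change peaks.
    """

    fit_without: LorentzianFit
    fit_with: LorentzianFit
    delta_lambda_nm: float
    lambda_max_nm: float
    dense_wavelengths_nm: np.ndarray
    delta_C: np.ndarray  # signed difference (with - without) on dense grid

    @property
    def delta_C_at_max(self) -> float:
        i = int(np.argmin(np.abs(self.dense_wavelengths_nm
                                 - self.lambda_max_nm)))
        return float(self.delta_C[i])

    def C_without(self, lam) -> np.ndarray:
        return self.fit_without(lam)

    def C_with(self, lam) -> np.ndarray:
        return self.fit_with(lam)


def binding_response(spec_without: Spectrum, spec_with: Spectrum,
                     fix_baseline: bool = False) -> BindingResponse:
    """Fit both states (shared wavelength grid) and extract observables.

    The dense difference curve is evaluated at 0.1 nm resolution and the
    search for lambda_max runs over lam > lambda_res(without); ties break
    toward the smaller wavelength.
    """
    if not np.array_equal(spec_without.wavelengths_nm,
                          spec_with.wavelengths_nm):
        raise ValueError("both states must share the same wavelength grid")
    fit0 = fit_lorentzian(spec_without, fix_baseline=fix_baseline)
    fit1 = fit_lorentzian(spec_with, fix_baseline=fix_baseline)

    # the fitted curves are evaluated (model-based, possibly slightly
    # beyond the sampled band) far enough past the bare resonance that the
    # long-wavelength flank is always available for the lambda_max search
    lam = spec_without.wavelengths_nm
    hi = max(lam[-1], fit0.lambda_res_nm + 1.5 * fit0.gamma_nm)
    dense = np.arange(lam[0], hi + DENSE_GRID_STEP_NM / 2,
                      DENSE_GRID_STEP_NM)
    delta = fit1(dense) - fit0(dense)

    mask = dense > fit0.lambda_res_nm
    # argmax returns the first (smallest-wavelength) maximum on ties
    i = int(np.argmax(np.abs(delta[mask])))
    lam_max = float(dense[mask][i])

    return BindingResponse(
        fit_without=fit0,
        fit_with=fit1,
        delta_lambda_nm=float(fit1.lambda_res_nm - fit0.lambda_res_nm),
        lambda_max_nm=lam_max,
        dense_wavelengths_nm=dense,
        delta_C=delta,
    )
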