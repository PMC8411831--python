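"""Steady-state nanoparticle heating and constant-temperature intensity.

The surface temperature rise of an illuminated metal nanoparticle in water
is dT = C_abs * I / (4 pi kappa R_eq beta), where R_eq is the radius of the
equal-volume sphere and beta is a dimensionless thermal capacitance
coefficient (1 for a sphere, growing as the shape elongates).  Inverting
the formula gives the illumination intensity each particle size tolerates
at a fixed temperature budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThermalParams", "steady_state_dT", "intensity_for_dT"]

KAPPA_WATER_W_M_K = 0.6

#: Default thermal capacitance vs aspect ratio for capped rods.  beta = 1
#: for a sphere and grows with elongation; these values are a smooth
#: placeholder consistent with boundary-element tabulations for rods and
#: are meant to be replaced via configuration when exact values are known.
BETA_TABLE_DEFAULT = {1.0: 1.00, 2.0: 1.08, 3.0: 1.18, 4.0: 1.28, 5.0: 1.37}


@dataclass(frozen=True)
class ThermalParams:
    kappa_w_m_k: float = KAPPA_WATER_W_M_K
    beta_table: dict = field(default_factory=lambda: dict(BETA_TABLE_DEFAULT))
    dT_target_K: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_w_m_k <= 0 or self.dT_target_K <= 0:
            raise ValueError("kappa and dT target must be positive")
        ar = np.array(sorted(self.beta_table))
        b = np.array([self.beta_table[a] for a in ar])
        if (b < 1.0).any() or (np.diff(b) < 0).any():
            raise ValueError("beta must be >= 1 and non-decreasing in AR")
        object.__setattr__(self, "_ar_nodes", ar)
        object.__setattr__(self, "_beta_nodes", b)

    def beta(self, aspect_ratio: float) -> float:
        """Linearly interpolated thermal capacitance coefficient."""
        return float(np.interp(aspect_ratio, self._ar_nodes,
                               self._beta_nodes))


def steady_state_dT(c_abs_um2: float, intensity_W_m2: float, r_eq_nm: float,
                    beta: float = 1.0,
                    kappa_w_m_k: float = KAPPA_WATER_W_M_K) -> float:
    """Surface temperature rise dT = C_abs I / (4 pi kappa R_eq beta), in K."""
    if min(c_abs_um2, intensity_W_m2, r_eq_nm, beta, kappa_w_m_k) <= 0:
        raise ValueError("all inputs must be positive")
    p_abs_W = c_abs_um2 * 1e-12 * intensity_W_m2
    return float(p_abs_W / (4.0 * np.pi * kappa_w_m_k * r_eq_nm * 1e-9 * beta))


def intensity_for_dT(c_abs_um2: float, r_eq_nm: float, beta: float = 1.0,
                     kappa_w_m_k: float = KAPPA_WATER_W_M_K,
                     dT_target_K: float = 1.0) -> float:
    """Intensity (W/m^2) producing a given steady-state temperature rise.

    Exact inverse of :func:`steady_state_dT`; errors on C_abs = 0.
    """
    if c_abs_um2 <= 0:
        raise ValueError("C_abs must be positive")
    return float(4.0 * np.pi * kappa_w_m_k * r_eq_nm * 1e-9 * beta
                 * dT_target_K / (c_abs_um2 * 1e-12))
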