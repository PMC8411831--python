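"""Synthetic fixtures: noisy two-state spectra and tiny solver scenes.

These generators reproduce the statistical structure the downstream
analysis assumes -- Lorentzian resonance lines sampled with Poisson photon
counting, and small voxel grids with closed-form or brute-force-checkable
solutions -- so the metrics pipeline and the solver can be tested
independently of each other.  All generators are seed-deterministic and
return the noiseless ground truth alongside the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (DipoleGrid, NanorodGeometry, ShellSpec,
                       build_scene, voxelize)
from .materials import MaterialSet
from .spectra import Spectrum

__all__ = [
    "SyntheticSpectrumSpec",
    "TwoStateSpectra",
    "make_two_state_spectra",
    "make_toy_grid",
]


@dataclass(frozen=True)
class SyntheticSpectrumSpec:
    """Two-state Lorentzian + shot-noise spectrum generator parameters.

    The bound state is the bare Lorentzian shifted by ``shift_nm``, with
    fractional amplitude and width changes ``amplitude_change`` and
    ``width_change``.  ``peak_counts`` sets the mean photon count at the
    bare peak (peak SNR = sqrt(peak_counts)).
    """

    lambda_res_nm: float = 800.0
    gamma_nm: float = 40.0
    c_max: float = 1.0
    baseline: float = 0.0
    shift_nm: float = 0.4
    amplitude_change: float = 0.0
    width_change: float = 0.0
    peak_counts: float = 1e4
    n_points: int = 15
    span_gammas: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_nm <= 0 or self.peak_counts < 0:
            raise ValueError("gamma must be > 0 and peak counts >= 0")

    def wavelength_grid(self) -> np.ndarray:
        half = self.span_gammas * self.gamma_nm
        return np.linspace(self.lambda_res_nm - half,
                           self.lambda_res_nm + half, self.n_points)


@dataclass(frozen=True)
class TwoStateSpectra:
    """Poisson-sampled count spectra plus the noiseless truth."""

    spec: SyntheticSpectrumSpec
    without: Spectrum
    with_molecule: Spectrum
    truth_without: Spectrum
    truth_with: Spectrum
    meta: dict = field(default_factory=dict)


def _lorentz_counts(lam, lam0, gamma, peak, baseline):
    hw2 = (gamma / 2.0) ** 2
    return baseline + peak * hw2 / ((lam - lam0) ** 2 + hw2)


def make_two_state_spectra(spec: SyntheticSpectrumSpec,
                           sample: bool = True) -> TwoStateSpectra:
    """Generate bound/unbound count spectra around analytic Lorentzians.

    ``sample=False`` returns the noiseless means in place of Poisson draws
    (the infinite-count limit).
    """
    lam = spec.wavelength_grid()
    scale = spec.peak_counts / spec.c_max if spec.c_max else 0.0
    mean0 = _lorentz_counts(lam, spec.lambda_res_nm, spec.gamma_nm,
                            spec.peak_counts, spec.baseline * scale)
    mean1 = _lorentz_counts(
        lam,
        spec.lambda_res_nm + spec.shift_nm,
        spec.gamma_nm * (1.0 + spec.width_change),
        spec.peak_counts * (1.0 + spec.amplitude_change),
        spec.baseline * scale,
    )
    if sample:
        rng = np.random.default_rng(spec.seed)
        c0 = rng.poisson(mean0).astype(float)
        c1 = rng.poisson(mean1).astype(float)
    else:
        c0, c1 = mean0, mean1
    return TwoStateSpectra(
        spec=spec,
        without=Spectrum(lam, c0, kind="counts"),
        with_molecule=Spectrum(lam, c1, kind="counts"),
        truth_without=Spectrum(lam, mean0, kind="counts"),
        truth_with=Spectrum(lam, mean1, kind="counts"),
        meta={"seed": spec.seed, "shift_nm": spec.shift_nm,
              "peak_counts": spec.peak_counts},
    )


def make_toy_grid(material_layout: str = "sphere",
                  voxel_size: float = 1.0) -> DipoleGrid:
    """Small (< 5000 voxel) grids with independently checkable solutions.

    Layouts: ``sphere`` (10 nm gold sphere in water, Mie-checkable),
    ``two_spheres`` (two well-separated 8 nm gold spheres) and
    ``rod_coarse`` (a 10 x 30 nm rod at a coarse lattice for smoke tests).
    All layouts disable the substrate and omit shell and molecule.
    """
    mats = MaterialSet()
    if material_layout == "sphere":
        scene = build_scene(NanorodGeometry(10.0, 1.0), ShellSpec(0.0),
                            materials=mats, substrate_enabled=False)
        return voxelize(scene, voxel_size)
    if material_layout == "two_spheres":
        # two spheres along x: a rod of AR 1 voxelized twice and merged
        scene = build_scene(NanorodGeometry(8.0, 1.0), ShellSpec(0.0),
                            materials=mats, substrate_enabled=False)
        g = voxelize(scene, voxel_size)
        shift = int(round(16.0 / voxel_size))  # 16 nm center separation
        idx = np.vstack([g.indices, g.indices + [shift, 0, 0]])
        mat = np.concatenate([g.material_id, g.material_id])
        nx, ny, nz = g.shape
        return DipoleGrid(
            voxel_size=g.voxel_size,
            origin=g.origin,
            shape=(nx + shift, ny, nz),
            indices=idx.astype(np.int32),
            material_id=mat,
            scene=scene,
        )
    if material_layout == "rod_coarse":
        scene = build_scene(NanorodGeometry(10.0, 3.0), ShellSpec(0.0),
                            materials=mats, substrate_enabled=False)
        return voxelize(scene, 1.25)
    raise ValueError(f"unknown layout {material_layout!r}")
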