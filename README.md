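# plasmonsense

Computational optimization of gold-nanorod biosensors for single-molecule
detection. A single protein binding to the tip of a gold nanorod shifts the
particle's localized surface plasmon resonance by a fraction of a
nanometer; whether that step is detectable depends as much on the photon
budget and noise as on the shift itself. This package models the full
chain — electromagnetics, spectral fitting, photon statistics — and
optimizes the nanorod size for three detection modalities. It is written
for biosensing and nanophotonics researchers who want a self-contained,
scriptable version of that analysis.

## Model and figures of merit

The sensor is a spherically capped gold nanorod (width *d*, aspect ratio
*AR*) with a 1.5 nm functionalization shell (*n* = 1.45) on glass in
water; the analyte is a 5 nm, *n* = 1.57 sphere (a 52.8 kDa protein at
1.37 g/cm³) bound at the tip. Scattering and absorption spectra with and
without the molecule are computed by the discrete dipole approximation
(FFT-accelerated coupled dipoles, lattice-dispersion polarizability,
quasi-static image treatment of the substrate) and summarized by
Lorentzian fits (λ_res, Γ, C_max).

Detectability of a binding step with signals *s₁, s₂* and noises
*σ₁, σ₂* is the contrast-to-noise ratio

    CNR = |s₂ − s₁| / √(σ₁² + σ₂²)

evaluated per modality in the shot-noise limit (SNR = √s):

* spectral: *s* = λ_res, σ_fit = η·Γ/SNR with η ≈ 0.21;
* fixed-wavelength scattering: counts at λ_max on the red flank,
  CNR_I = |ΔC_scat|·√(Φ·Δt) / √(C₁+C₂);
* photothermal: signal ∝ ΔC_abs·I_heat, noise set by the probe beam.

Noise-independent FOMs (Δλ/Γ and max |ΔC|/C) are computed alongside. A
steady-state heating model ΔT = C_abs·I/(4πκ·R_eq·β) supports sweeps at
constant temperature rise instead of constant illumination. See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Coarse desk-scale run (d/8 voxels, point-dipole molecule, homogeneous
water host) for the 20 × 80 nm reference rod:

```python
from plasmonsense import (NanorodGeometry, MoleculeSpec, build_scene,
                          DetectionConfig, SolverSettings,
                          SpectrumPlan, compute_binding_responses,
                          modality_cnrs)

plan = SpectrumPlan(voxel_fraction=1/8,
                    molecule_representation="point_dipole",
                    n_wide=0, n_fine=5, fix_baseline=True,
                    settings=SolverSettings(tolerance=3e-4,
                                            substrate_model="none",
                                            single_precision=True))
scene = build_scene(NanorodGeometry(20.0, 4.0), molecule=MoleculeSpec(),
                    substrate_enabled=False)
cell = compute_binding_responses(scene, plan)
r = cell.response_scat
print(f"lambda_res = {r.fit_without.lambda_res_nm:.0f} nm, "
      f"Gamma = {r.fit_without.gamma_nm:.0f} nm, "
      f"delta_lambda = {r.delta_lambda_nm:.3f} nm")
for name, res in modality_cnrs(cell, DetectionConfig()).items():
    print(f"{name}: CNR = {res.cnr:.3g} at {res.sensing_wavelength_nm:.0f} nm")
```

prints

```
lambda_res = 872 nm, Gamma = 57 nm, delta_lambda = 0.148 nm
spectral: CNR = 555 at 872 nm
fixed_wavelength: CNR = 220 at 888 nm
photothermal: CNR = 4.41e-11 at 888 nm
```

The single molecule shifts the resonance by 0.148 nm — far below the
57 nm linewidth, yet at the default photon budget (10⁷ W/m², 10 ms) the
step stands hundreds of noise standard deviations above the shot-noise floor
for spectral and fixed-wavelength detection. (The photothermal CNR is in
arbitrary units — its thermal-lens constant is an opaque scale factor, so
only relative comparisons across sizes are meaningful.) The coarse lattice
red-shifts absolute resonance positions; production runs use the 0.25/0.5
nm voxel rule, the substrate model and a voxelized molecule.

The same pipeline drives the size maps and parameter scans:

```bash
plasmonsense sweep --coarse --out runs/sweep    # CNR maps, 3 modalities
plasmonsense scan --variable diameter --coarse  # CNR vs molecule size
plasmonsense eta --seed 1 --trials 3000         # Monte-Carlo eta
```

On the coarse 4×4 grid all three modalities peak at an interior width of
20 nm (AR 4–5) while the noise-free FOMs peak at the smallest width — the
optimum is a genuine trade-off between field confinement (small rods shift
more) and photon budget (large rods scatter more). The CNR grows with
molecule diameter as a power law with exponent ≈ 2.3 and decays
exponentially with shell thickness.

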