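# Methods

## The model

A single-molecule plasmonic biosensor is modelled as a spherically capped
gold nanorod (width `d`, aspect ratio `AR`, length `D = AR·d`) wrapped in a
1.5 nm dielectric shell (`n = 1.45`, the PEG functionalization/passivation
layer), resting on a glass half-space (`n = 1.52`) and immersed in water
(`n = 1.33`). The analyte is a dielectric body of `n = 1.57` (water-free
streptavidin) whose volume equals that of a 5 nm sphere — the closely packed
sphere equivalent of a 52.8 kDa protein at 1.37 g/cm³. The molecule rests on
the outer shell surface at a binding site parameterized in 15° steps on the
hemispherical caps (indices 0–6) and 5 nm steps along the cylinder (7–12,
with 12 the midpoint of the 80 nm reference rod). Gold dispersion uses the
Johnson–Christy (1972) table, linearly interpolated in `n` and `k`; all
other materials are non-dispersive.

## Electromagnetics

Scattering and absorption cross sections come from the discrete dipole
approximation: the scene is voxelized on a cubic lattice (center-in-solid
membership, priority gold > molecule > shell > ambient), each voxel carries
a Clausius–Mossotti-type polarizability relative to water — the lattice
dispersion relation by default, radiative-reaction-corrected CM as an
alternative — and the coupled system is solved iteratively (lgmres with
Jacobi preconditioning, bicgstab fallback; relative residual 1e-5 by
default) with an FFT-accelerated matrix–vector product. `C_ext` comes from
the optical theorem, `C_abs` from the per-dipole absorption sum,
`C_scat = C_ext − C_abs`. A Lorenz–Mie series (Bohren–Huffman recurrences)
serves as an independent oracle for spheres.

The glass substrate is treated in a quasi-static image approximation:
every dipole interacts with its mirror image weighted by
`(ε_glass − ε_water)/(ε_glass + ε_water)` (tangential moment components
flipped), and the incident plane wave acquires its normal-incidence Fresnel
reflection. This reproduces the qualitative substrate effects (red-shift,
broken vertical symmetry) at a small fraction of the cost of rigorous
surface Green's functions; absolute resonance positions therefore carry a
model error relative to a Sommerfeld-integral treatment, and all
substrate-dependent comparisons should be read as model-approximate.

Accuracy: for a weakly contrasting lossy dielectric sphere the solver
converges to the Mie oracle at ~1% by `h = r/10`. For gold the
staircase-surface error dominates off resonance (tens of percent at 0.5 nm
voxels near 600 nm, decaying roughly linearly in `h`) while agreement near
the plasmon band — the regime every sensing quantity is evaluated in — is
at the percent level. This is the standard behaviour of DDA for
high-contrast metals and the reason production runs use 0.25 nm voxels for
rods up to 20 nm wide and 0.5 nm above.

### Sub-voxel molecules

At coarse lattices a 5 nm molecule spans less than one voxel and
center-membership voxelization quantizes the two-state difference signal to
zero or one voxel. For such runs the molecule can be represented as a
single off-lattice polarizable point (equal-volume-sphere Clausius–Mossotti
polarizability with radiative reaction) coupled densely to the lattice.
This preserves the binding-induced shift/amplitude structure at any lattice
spacing; it cannot represent molecule shape, and its own substrate image is
neglected. The production default remains full voxelization.

## Resonance descriptors

Spectra are sampled near the longitudinal peak (an adaptive coarse scan
locates it; a three-point inverse-quadratic solve — exact for a
baseline-free Lorentzian — seeds the window) and fitted with
`L(λ) = baseline + C_max (Γ/2)² / ((λ−λ_res)² + (Γ/2)²)` by least squares
in normalized coordinates. Binding observables: `Δλ = λ_res(with) −
λ_res(without)`; the signed difference of the fitted curves on a 0.1 nm
grid; `λ_max = argmax |ΔC(λ)|` restricted to the long-wavelength flank of
the bare resonance (ties toward shorter wavelength).

## Sensing metrics

Registered counts `s = Φ·bw·A_NP·A_SYS·A_DET·Δt` with
`Φ = I₀/hν` per nm of bandwidth; noise components σ_sys (config),
`σ_det = sqrt(I_D Δt + σ_R²)`, shot noise `√s`; in the shot-noise limit
`SNR = √s`. The universal figure of merit is
`CNR = |s₂ − s₁| / sqrt(σ₁² + σ₂²)` (root-sum-of-squares combination of the
two states' independent noises).

* **Spectral**: signal is the fitted peak position; its noise is
  `σ_fit = η·Γ/SNR`. The constant η is reproduced by Monte Carlo:
  Poisson-noised Lorentzian spectra fitted with the same pipeline. η depends
  on the sampling density; 21 points across ±1.2Γ (the default) give
  η ≈ 0.22 in the large-trial limit, consistent with the canonical 0.21,
  and the value is flat in Γ and SNR. Both the state-specific CNR and the
  one-state simplification `Δλ·SNR₁/(η·Γ₁·√2)` are reported.
* **Fixed-wavelength scattering**: counts at `λ_max`;
  `CNR_I = |ΔC|·sqrt(Φ·bw·Δt)/sqrt(C₁+C₂)`. The reported simplification is
  `(|ΔC|/C₁)·SNR₁/√2` evaluated at `λ_max` (both noises approximated by the
  bare state); the global maximum of `|ΔC|/C` generally sits at a different
  wavelength, so the literal product of the noise-free FOM with the SNR is
  only proportional, not equal.
* **Photothermal**: pump at `λ_max` of the absorption difference; signal
  `Φ_probe·bw·C_th·ΔC_abs·I_heat·Δt`, noise `sqrt(Φ_probe·bw·A·Δt)` from
  the probe alone, so CNR is linear in `I_heat` and in `ΔC_abs`. `C_th` and
  the detector area are opaque constants (default 1 and 1e-12 m²): only
  relative photothermal CNRs are meaningful.

Noise-independent FOMs: `FOM_λ = Δλ/Γ` and `FOM_I = max_λ |ΔC(λ)|/C(λ)`.

## Thermal limit

Steady-state surface temperature rise `ΔT = C_abs·I/(4π·κ·R_eq·β)` with
`R_eq` the equal-volume-sphere radius (computed exactly from the capped-
cylinder volume), `κ = 0.6 W/m/K` for water, and β(AR) a dimensionless
thermal capacitance (1 for a sphere, increasing with elongation). Exact β
values for capped rods are not available here; the shipped table
{AR 1→1.00, 2→1.08, 3→1.18, 4→1.28, 5→1.37} is a smooth monotone
placeholder, replaceable via configuration. Constant-temperature sweeps
invert the formula per cell, evaluating `C_abs` at each modality's own
sensing wavelength (the heating beam for photothermal, where `I_heat` is
rescaled instead of the probe).

## Sweeps and scans

The size sweep covers widths 10–40 nm and AR 2–5 (production steps 1 nm and
0.1) and reports, per modality, raw and max-normalized CNR maps, the
sensing wavelength per cell, the argmax cell, and 90/95% regions. Scans
vary one parameter around the 20 × 80 nm reference rod: binding-site index
(normalized to the tip), molecule diameter (log–log power-law fit),
RI contrast (linear fit with R²), molecule shape at equal volume
(normalized to the sphere), and shell thickness/RI (exponential decay fit
vs a linear competitor). Scans that alter only the molecule reuse the bare
spectrum; shell scans recompute both states.

The molecule-shape menu realizes "increasingly surface-hugging" contact
geometries at fixed volume: sphere; hemisphere (base on the shell);
spherical segment with height 0.6 R (flatter than a hemisphere); and a
concave spherical segment — a 20°-half-angle patch whose inner face
conforms to the outer shell sphere at the tip. The 20° angle gives the
patch a lateral size comparable to the reference sphere on the 20 nm rod.

## Problem sizes used by the test and acceptance runs

Desk-scale runs use voxel = d/8 (the coarsest the voxelizer accepts), the
point-dipole molecule, the homogeneous water host, 5-point fine spectra
with the baseline pinned to zero, solver tolerance 3e-4 in single
precision, and a 4×4 size grid (widths 10–40 nm, AR 2–5). At this scale the
coarse lattice red-shifts resonances substantially relative to experiment
(e.g. the 40 × 200 rod peaks near 1.2 µm), but the structural results —
the interior CNR optimum near 20 nm width, FOM maxima at the smallest
width, the tip-to-side sensitivity decay, linear RI response, exponential
shell-thickness decay — are the quantities these runs are designed to
exhibit, and they are the ones asserted. Quantitative production-fidelity
values require the production voxel sizes and the substrate model and are
not asserted by the test suite.

What the synthetic two-state generator emulates: Lorentzian resonance
lines, a rigid shift plus small amplitude/width changes on binding, and
Poisson photon counting. It does not emulate correlated system noise,
detector fixed-pattern noise, spectral baselines from instrument response,
or non-Lorentzian lineshapes; passing its tests validates the metrics
pipeline, not detector modelling.

## Numerical choices and degenerate inputs

Voxelization requires `h ≤ d/8` (warns above `d/16`); `AR = 1` degenerates
cleanly to a sphere; a zero-thickness shell and an absent molecule are
valid. Lorentzian fits require an interior maximum and at least 5 points;
ties in the `λ_max` search break toward shorter wavelength; `C_scat < 0`
beyond tolerance is clipped to zero with a warning. Systems of ≤ 2 dipoles
are solved densely (exactly). All randomness flows through explicit seeds;
solver and sweep outputs are deterministic for a fixed configuration.

## Known limitations

Quasi-static substrate images instead of rigorous surface Green's
functions; no angular-collection (NA) modelling (`A_SYS = 1`); η assumes
unweighted least-squares fitting of shot-noise-limited spectra; β(AR) is a
placeholder; photothermal constants are opaque; coarse-lattice runs are
structurally but not spectrally faithful; single molecules only, with no
mass transport, surface chemistry, or transient heating.
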