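# Methods

## Scope and model chain

The package computes peripheral-nerve stimulation thresholds for whole-body
uniform magnetic-field exposure by chaining four models:

1. **Volume conductor** — a voxel tissue-label grid.  Anatomical voxel
   models are licensed and not redistributable, so the packaged phantom is
   an elliptical-cylinder torso with concentric skin (2 mm), subcutaneous
   fat (10 mm) and muscle shells plus a posterior cortical-bone column.
   The section is 1.5× wider laterally than front-to-back, like a human
   trunk; this is what makes front-to-back exposure the worst case, since
   the induced-current loops lie in the wide lateral–vertical plane
   perpendicular to **B**.  Coordinates: 0-based voxel indices, voxel
   center at `origin + (index + 0.5)·voxel_size`, x = left–right,
   y = front–back, z = inferior–superior.

2. **Tissue conductivity** — the 4-Cole-Cole dispersion model evaluated at
   the exposure frequency; only the conduction part Re[jωε₀ε̂(ω)] is used
   (conduction currents dominate displacement currents by an order of
   magnitude below 1 MHz).  Constants for skin (dry), fat, muscle and
   cortical bone ship as a CSV transcribed from the standard literature
   parameterization and are config-replaceable.  Because the published
   study does not print its conductivity values, absolute field magnitudes
   on the phantom cannot be checked against it; the solver is instead
   validated against closed forms (below).

3. **Induced field (SPFD)** — one Kirchhoff equation per node of the voxel
   lattice, edge conductance s = σ̄·Δ with σ̄ the arithmetic mean of the up
   to four voxels sharing the edge (air contributes zero).  With purely
   real σ the source term is purely imaginary, so φ = jωψ reduces the
   system to a real, symmetric positive-semidefinite one, solved by
   Jacobi-preconditioned conjugate gradients (default relative residual
   1e-6) with the constant-potential nullspace projected out; this
   reduction is exact, not an approximation.  Per-voxel field amplitude:
   E = ω|∇ψ + A₀|, ∇ψ averaged over the four parallel edges per axis,
   A₀ = ½B×(r−r_c) in the symmetric gauge about the conductor centroid.
   Peak convention throughout; `InducedField.e_rms()` gives peak/√2 for
   rms-based limits.  Only cubic voxels are supported.  Validation: the
   homogeneous circular cylinder under axial exposure (|E| = πfBr, error
   <0.3% at 2 mm) and the elliptical section closed form ψ = kxy,
   k = (B/2)(b²−a²)/(a²+b²), under which the discretization error falls
   monotonically from 4 mm to 1 mm voxels.

4. **Axon dynamics** — a SENN-family compartment chain (alternating nodes
   of Ranvier and internodes, internode length 100×D, nodal gap 1.5 μm,
   axon diameter 0.7×D) with CRRSS nodal membrane: sodium m²h kinetics
   (rates at 37 °C, Q10 = 3) and linear leak; internodes are passive.
   Integration is Crank–Nicolson on the cable with exponential-Euler
   gating (dt = 1 μs for pulses, ≤ T/50 for sinusoids); the extracellular
   drive enters as the axial-difference stencil applied to the
   quasi-potential (activating-function form).  Activation = at least four
   adjacent nodes depolarizing beyond +80 mV with strictly ordered
   first-crossing times (a propagating spike, not a stimulus artifact);
   "strictly ordered" is our reading of the detection rule — ties are
   rejected.

## Axon parameter conventions

The published lumped parameter table is internally inconsistent: nF-scale
capacitances with kΩ-scale axial resistances imply ~10 ms nodal time
constants, irreconcilable with the 360 μs chronaxie the same model is said
to reproduce, and the printed internode capacitance (28.8) equals the
myelin capacitance of a 20 μm × 2 mm internode in **pF** (we compute
28.9 pF), suggesting a units slip.  `AxonParams.from_geometry` (the
default everywhere) therefore derives lumped elements from per-area CRRSS
constants and SENN geometry:

| quantity | value | note |
|---|---|---|
| g_Na | 1445 mS/cm² × nodal area | CRRSS |
| g_l | 128 mS/cm² × nodal area | CRRSS |
| c_node | 2.5 μF/cm² × nodal area | CRRSS |
| axoplasm resistivity | 110 Ω·cm | SENN convention |
| internode C, G | 28.9 pF, 26.8 nS at 20 μm, ∝ D | constant g-ratio |
| E_Na | 115 mV | |
| E_leak | auto-balanced | see below |

`AxonParams.from_table` keeps the printed lumped values verbatim for
auditability.  Internode elements scale linearly with diameter (a constant
g-ratio makes the lamella count ∝ D), which together with the fixed nodal
gap yields activation thresholds ∝ 1/D — the scaling law the threshold
literature assumes; we measure a 10 μm/20 μm threshold ratio of 2.02.

The leak reversal is computed per parameter set so that the resting state
is an exact equilibrium of the nodal membrane (the sodium window current
at rest is cancelled by the leak).  For the unmultiplied parameter set
this reproduces the published −0.01 mV figure (−0.0106 mV computed); for
multiplied sets the published value would leave a ~0.3 mV rest drift.

Response presets (`perceptual`: C×6.0, G_Na×8.0, G_l×0.25;
`uncomfortable`: C×8.5, G_Na×4.5, G_l×0.25) implement the calibrated
response classes; `calibrate_params` re-derives such multipliers for new
targets by coordinate descent over multiplier grids, minimizing
max(|b−b*|/b*, |C−C*|/C*) under the uniform-field protocol.

### Calibration fidelity, honestly stated

With the perceptual preset, the uniform-field nine-width bipolar protocol
fits **b = 3.28 V/m, C = 360 μs**.  The chronaxie matches the 360 μs
experimental target because the multipliers pin the nodal time constant
(τ = c·6.0/(g_l·0.25) ≈ 469 μs); this is robust across every parameter
convention we examined.  The rheobase sits ~32% below the 4.8 V/m target.
The original calibration was performed *in situ* in a licensed anatomical
model (non-uniform field sampled along a curved fiber at a field hotspot),
whereas our arena is the reproducible straight-fiber/uniform-field setup;
no literature-standard morphology (axoplasm resistivity 54.7–110 Ω·cm,
axon/fiber ratio 0.5–0.7, nodal gap 1.5–2.5 μm, internode capacitance
5–29 pF) raises the uniform-field rheobase above ~3.8 V/m.  We report the
discrepancy rather than rescale; it propagates to the
uncomfortable/perceptual fitted-rheobase ratio (1.26 here vs. 1.5
experimentally).  The unmultiplied (base) parameter set does not conduct a
propagating spike with the 29 pF internode capacitance — all study use is
through the calibrated presets, which propagate robustly.

## Strength–duration protocol and fitting

Bipolar rectangular pulse pairs (positive phase of width w, 300 μs gap,
mirrored negative phase) at widths 20, 50, 100, 150, 200, 300, 500, 700,
1000 μs; thresholds by bisection on the drive amplitude (log-spaced
bracketing from default bounds [1e-3, 1e3], returning the activating upper
bound at 1% relative bracket width — conservative).  The hyperbolic law is
fitted by linear least squares on (b, bC) with residuals weighted by 1/I:
threshold scatter is multiplicative and thresholds span a decade, and the
weighted fit recovers b within ~4% under 5% noise where the unweighted fit
can err by >30%.  The fit is exact on noise-free hyperbolic data.
Sinusoidal thresholds use ≥10 cycles or ≥2 ms of drive, whichever is
longer.  `convert_rheobase` maps external dB/dt rheobases to internal-field
values through the proportionality E_th/E_sim = (dB/dt)_th/(dB/dt)_sim.

## Field reduction, hotspots, fibers

* 2-mm cubic averaging: non-overlapping cubes, component-wise vector mean
  then magnitude, cubes spanning more than one tissue excluded; the
  per-tissue compliance value is the 99th percentile (linear interpolation
  between closest ranks — stated because conventions differ).
* 5-mm line averaging: per voxel, the mean projection of **E** on a 5 mm
  segment centered there along the *local field direction* (a scan over
  all directions would cost orders of magnitude more and the field
  direction dominates the maximizing direction); segments leaving the
  tissue are excluded.
* Hotspots: top-n averaged values within fat/skin (the standards'
  surrogate tissue for peripheral nerves) with a 10 mm minimum mutual
  separation so the set spans distinct regions; the separation rule is our
  convention — the study's spacing rule is unstated.
* Straight fibers lie in the surface tangent plane at the hotspot (normal
  from the local air-mass direction), rotated anticlockwise from the
  projected body z-axis in steps of 30° (0–180°); whether the original
  fibers lay in a tangent plane is unstated, so the choice is recorded in
  fiber metadata.  Curved fibers are bidirectional streamlines of **E**
  (adaptive RK on the trilinearly interpolated field), truncated
  symmetrically where the field magnitude falls below 5% of its center
  value (which includes leaving the conductor).  Quasi-potentials are
  trapezoid line integrals on ≤0.2 mm subdivisions, reported on a 1 mT
  exposure basis so threshold amplitudes are directly external flux
  densities.

## Limits and margins

Limit curves are data (YAML fixtures with citation and peak/rms flags),
piecewise a·f^p + c: ICNIRP 2010 occupational reference levels (external
B, rms) and basic restrictions (internal E, rms), IEEE C95.1
restricted-environment ERL (external B, rms, head and torso) and PNS DRL
(internal E, peak, 5-mm line convention; whether the comparable published
figure uses peak or rms is unstated, hence the explicit flag).  Margins
compare peak-convention thresholds to peak-converted limits pointwise and
report the band minimum.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations chosen as
the package's own defaults: 2 mm phantoms of 60–120 mm radius for field
validation (1 mm only in the grid-convergence check), 21-node fibers for
calibration, 8–10-node fibers in pipeline smoke runs, and frequency sweeps
at a few points in 1–10 kHz (each frequency re-solves conductivity and
field, since σ(f) drifts).  Every stage is deterministic given the config;
the only randomness (subsampling of fiber groups for median-convergence
statistics) is seeded, and the seed is recorded in the run manifest.

## Known limitations

* The phantom is a geometric torso: hotspot anatomy (underarm/crotch/neck
  concentrations) and absolute thresholds of human-model studies are out
  of reach; passing tests demonstrate correct mechanics, scaling behavior
  and qualitative field structure, not anatomical dosimetry.
* Dry-skin Cole-Cole conductivity is very low at low frequency; real
  low-frequency skin conductivity is contested, and the fixture is meant
  to be swapped when that matters.
* No multigrid acceleration: plain preconditioned CG is adequate at these
  problem sizes.
* Unmyelinated fibers, branching fibers, anisotropic conductivity,
  posture/size variation and thermal (>100 kHz continuous) effects are out
  of scope.
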