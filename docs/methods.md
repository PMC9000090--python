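# Methods

## Model family

`actogel` implements one chemistry embedded in three mechanical settings.

**Chemistry.** RhoA (`r`, the fast-diffusing activator) is produced at a
basal rate `S` (GEF activity), amplifies itself through a saturating
autocatalytic term `a rⁿ/(r_aⁿ + rⁿ)` (Hill exponent `n`, default 1 — the
Michaelis form), and is inactivated by actomyosin-recruited GAPs at rate
`g m r/(r_g + r)`.  Actomyosin (`m`, the slow-diffusing inhibitor and force
generator, one species standing in for F-actin + myosin-II, justified by
their near-identical cortical turnover) is produced as `S_m + k_a r²` and
disassembles at `k_d m`.  Default rate constants are the values calibrated
on *C. elegans* cortex data:

| parameter | value | units |
|---|---|---|
| S | 0 | 1/s |
| a | 0.1609 | 1/s |
| n | 1 | – |
| r_a | 0.3833 | conc. |
| g | 0.1787 | 1/s |
| r_g | 0.01 | conc. |
| S_m | 0.0076 | 1/s |
| k_a | 0.1408 | 1/s |
| k_d | 0.0828 | 1/s |

The inhibition term carries exponent 1 in `r` (the `r/(r_g+r)` form); only
the autocatalytic term is given a general Hill exponent, since only `n` is
listed as a parameter of the chemistry.

**Local (well-mixed) model.** A Kelvin–Voigt patch with strain `u`,
relaxation time `η_L/E` (default 5 s) and relative contractility `σₐ/E`
(default 0.2).  Strain rate feeds back on both concentrations through
dilution, `ċ = R_c − c u̇/(1+u)`, which conserves `c(1+u)` exactly when
reactions are off.  `m₀`, the actomyosin level at half-maximal stress, is
not fixed by the calibrated data; we set `m₀ = 1` (the order of the
steady-state concentrations) and expose it as a parameter.

**Continuum models.** The cortex is a porous Maxwell gel; eliminating
cytosolic pressure and drag leaves a velocity equation containing only the
relaxation time τ = 5 s, the hydrodynamic length λ = √(η/γ) = 14.3 μm, and
the γ-scaled active stress σ' = σₐ/γ = 49.8 μm²/s by default.  Diffusivities
are D_r = 0.1, D_m = 0.01 μm²/s.  In 2D the viscosity splits into bulk and
shear parts, η_b = 3η/4 and η_s = η/4, with a common relaxation time; a
y-invariant 2D field then feels exactly the 1D operator (the reduction is
tested to machine precision).  Working units throughout: μm, s,
dimensionless concentrations, γ-scaled stresses.

## Numerics

Ordinary differential equations use SciPy's adaptive RK45 (`rtol 1e-8`).
The PDE solvers use operator splitting per inner step:

1. **Velocity.** Backward-Euler in time, exact per Fourier mode on the
   periodic grid.  In 2D the operator is diagonalised by the
   longitudinal/transverse split of v̂(k); the active forcing
   σ'∇[m/(m₀+m)] is purely longitudinal.
2. **Transport.** Conservative finite-volume fluxes, upwinded on the face
   velocity, with a MUSCL/van Leer limited reconstruction including the
   Courant-number time-centring term (second order in smooth regions,
   positivity preserving, no phase error for uniform advection).  First
   order donor-cell is available as `limiter='upwind'`; at 150 cells its
   extra numerical diffusion makes stationary localized pulses drift
   slowly, which is why the limited scheme is the default.  Diffusion is
   applied as the unconditionally stable spectral factor 1/(1 + Δt D k²),
   which leaves the spatial mean untouched, so transport conserves mass to
   round-off.
3. **Reaction.** Heun (RK2) with the spatially local stimulus S(x, t),
   clipped at zero.

The inner step is bounded by `dt_max = 0.25 s` and an advective CFL of 0.5;
output is sampled at a fixed 1 s cadence.  Blow-up (any field above 1e6)
raises with diagnostics.  Grid default: 150 cells per dimension, box
L = 10λ.  Tests and reduced-scale statistics runs use 48–128 cells and
shorter boxes where the behaviour under test is insensitive to them.

## Initial conditions

The headline behaviours depend on how the system is started, and no
single start suits all regimes:

* **Empty cortex** (r ≈ 0 trace noise, m = 0): the default for sustained
  stimuli.  Starting below the basal actomyosin level leaves the GAP brake
  off, so switching on S fires the excitable pulse; starting *at* the basal
  steady state sits inside the excitation threshold and the S = 0.002
  excitable regime would misreport as quiescent.
* **RhoA bump / ignition field**: at S = 0 nothing fires spontaneously (the
  rest state is linearly stable even at high σ'), so stationary-pattern
  experiments are triggered by a localized RhoA bump (1D) or by a
  RhoA-loaded field with band-limited noise (correlation length λ/3,
  relative amplitude 0.6) in 2D, mimicking the spatial structure of a
  triggering pulse that contractile flows then amplify into clusters and
  networks.
* **Rest + small noise**: low fixed point with 1% multiplicative noise,
  for linear-regime experiments.

All random fields are generated from a seeded `numpy` Generator and the
seed is recorded in every output's attributes.

## Classifiers

Regime labels are decision trees on simulated trajectories, with thresholds
chosen for robustness rather than tuned per case:

* **Local model**: prominence-filtered maxima of m(t) (prominence ≥ 10% of
  range).  ≥3 late non-decaying peaks → pulsatile; decayed excursions →
  excitable or contractile by whether the final state sits below or above
  the middle (saddle) branch when three fixed points exist; with a single
  fixed point, ringing → contractile, monotone → quiescent.
* **1D gel**: spatial coefficient of variation of m separates uniform from
  patterned (threshold 0.05).  Uniform states are classified by their
  spatial mean like the local model.  Patterned states are stationary
  (per-pixel temporal std < 5% of contrast, or peak track confined within
  λ/2 — the latter admits marginally-resolved peaks that breathe in
  amplitude on coarse grids) → localized-contraction; moving patterns are
  split by a localization statistic ⟨max m/mean m⟩ (> 3.25 → pulsatile
  flows, the "small intense foci" morphology) and spectral periodicity of
  the mean (waves are periodic).
* **Local activation (boxcar stimulus)**: the protocol applies
  S = 0.03 s⁻¹ in a central box of width λ for 100 s starting at t = 50 s
  (box width and duration are not constrained by the calibrated data; one
  hydrodynamic length and ~10 pulse periods reliably entrain the box
  interior).  The late-time RhoA profile decides the class: mostly-high
  domain → bistable front; back to rest → soliton; persistent localized
  peak → stable localized.

## Phase-field analysis

Oscillation phase is φ = atan2(r − r̄, m − m̄) with r̄, m̄ the space–time
means of the analysis window (per-pixel temporal means are available); the
four-quadrant form makes φ wind monotonically on the limit cycle.  Defects
are plaquette windings of branch-wrapped phase differences; on the torus
the total charge vanishes identically, and charges are provably within
{−1, 0, +1} because each wrapped edge difference lies in (−π, π].

Phase velocity v_φ = ∇φ is computed two ways: centred wrapped differences
(smooth maps, used for vorticity and energy–enstrophy) and one-sided
face-centred differences (`scheme='face'`) for speed statistics.  The face
scheme samples the 1/r speed halo around defect cores down to half a cell;
on synthetic vortex-gas fields with an exact v⁻³ speed tail it recovers
exponent 3.0 while the centred scheme distorts the core and misestimates
the tail — this validation on synthetic ground truth fixed the choice.
Vorticity is spectral by default (exact for band-limited fields, so a
single Fourier mode satisfies Ω̄/Ē = k² to round-off).

The tail exponent is a continuous maximum-likelihood power-law fit above a
lower cutoff chosen by KS-distance minimisation within the top 5% of
samples, after normalising speeds by their mean.  Gridded phase gradients
saturate near π/Δx, so speeds above 0.25 π/Δx are excluded and the
truncated-power-law likelihood is used; the poor-fit flag compares the KS
distance with the 5% critical value 1.36/√n.

## Scales used for statistics

The turbulence statistics in the test suite run the 2D model at its native
scale (150² cells, L = 10λ, 700 s, analysis window from 300 s) for the
speed tail, and at 96² cells, 500 s for the energy–enstrophy scan over
σ' = 50…100 μm²/s; per-run time-averaged (Ē, Ω̄) pairs are fit by ordinary
least squares.  These sizes give ≥10⁴ tail samples and stable statistics
while keeping a full test run within minutes.

## Linear stability conventions

The plane-wave stability matrix couples (δr, δm, δv) with diffusive damping,
advective couplings −ikr*, −ikm*, the active-stress coupling
ikσ'm₀/(τ(m₀+m*)²), and mechanical relaxation −(1+λ²k²)/τ (the viscosity in
that entry is the network viscosity η, the dimensionally consistent
reading).  When three fixed points exist the analysis linearises about the
low-(r, m) branch — the resting cortex.  The fastest-growing mode is
reported with the standard conventions wavelength 2π/k* and wave speed
Im λ(k*)/k*; an alternative printed normalisation (1/(2πk*) and
Im λ/(2πk*)) is available behind `alt_convention=True`.

## What the synthetic fixtures do and do not capture

Vortex fixtures (single, pair, plane wave) are exact phase geometries for
validating detectors; they are not solutions of the gel model.  The
igniter initial condition emulates the spatial structure of a triggering
pulse, not any measured cortical state; conclusions about *which* patterns
form are therefore robust, while pattern geometry at finite times inherits
the noise realisation.  No fixture models measurement noise, membrane
curvature, or cortical thickness variation — real-data pipelines would
need all three.

## Known limitations

* 1D/2D geometries are flat and periodic; no spherical-cortex curvature,
  no coupling to cell-shape change.
* The advection scheme's limiter clips smooth extrema by a few percent
  per λ of travel; wave amplitudes are slightly conservative at 150 cells.
* Near defect cores the phase is resolved only to the grid scale; speed
  statistics above 0.25 π/Δx are deliberately discarded.
* Regime boundaries in phase diagrams are classifier-based and can carry
  ±1 grid-cell ambiguity near onsets; low-confidence labels are flagged
  rather than silently assigned.
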