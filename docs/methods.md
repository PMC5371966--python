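# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying procedures are
genuinely open to interpretation.

## Units and constants

All internal quantities use nm, ps, kJ·mol⁻¹, elementary charges and
Kelvin. k_B = 0.00831446 kJ·mol⁻¹·K⁻¹, so k_BT ≈ 2.494 kJ·mol⁻¹ at the
default T = 300 K. Conversions appear only at reporting boundaries and are
each pinned by a unit test:

* e·V → kJ·mol⁻¹: 96.485 (binding-constant Boltzmann factor);
* kJ·mol⁻¹·nm⁻² → J·nm⁻²: 10³/N_A (interdigitation coefficient);
* e/(ε₀·nm) = 18.095 V per e·nm⁻¹ (electrostatic double integration);
* nm²·ps⁻¹ = 10⁶ × 10⁻⁸ cm²·s⁻¹ (diffusion coefficients).

## Trajectory model and preprocessing

Frames are time-stamped coordinate arrays with a per-frame orthorhombic
box; only orthorhombic periodicity is supported. Two text dialects are read
and written: multi-frame GRO (fixed-width, box line per frame) and
XYZ-with-box (count line, comment carrying `time=` and `box=`). The
generators emit the same formats the readers consume, so round-trip I/O is
exercised by every on-disk closure test.

**Membrane centering.** The procedure must cope with a bilayer split
across the periodic z boundary. A scan over 64 candidate wrap origins
selects the shift minimizing the wrapped lipid z-extent; the lipid mean z
is then subtracted and all z remapped into [−L_z/2, L_z/2). This is
idempotent and leaves x, y untouched. The bin-scan granularity (L_z/64) is
far finer than the water gap that separates periodic bilayer images, so the
minimizer is unambiguous in practice.

**Leaflets.** Each lipid is assigned by the sign of its phosphorus z after
centering; z = 0 exactly goes to the lower leaflet (an arbitrary but fixed
and tested tie-break). A monolayer-like assignment (all lipids on one
side) is logged as a warning rather than an error.

## Error estimation

Time-series observables use block averaging: the series is split into n
blocks for every n in 5..20 and the reported error is the maximum over the
scan of the standard error of block means, a plateau heuristic that is
within ~30% of the exact standard error for i.i.d. data and correctly
inflates for autocorrelated series (validated against the analytic
effective-sample-size result for an AR(1) process). Where only two
half-simulation estimates exist, the error is |a−b|/2 (the two-sample
standard error). Derived quantities propagate these in quadrature.

## Density profiles and landmarks

Profiles use a fixed grid of bins spanning [−⟨L_z⟩/2, ⟨L_z⟩/2) (default
500 bins, ≈0.017 nm at L_z ≈ 8.5 nm) with each frame's histogram
normalized by that frame's L_x·L_y·Δz, since the lateral box fluctuates
under semi-isotropic pressure coupling.

* **D_HH** is the distance between the raw phosphorus-density bin maxima
  on the two sides of z = 0, ties broken toward larger |z|; no smoothing
  is applied. A guard rejects profiles whose two "peaks" have no density
  dip between them (a single central peak is not a bilayer).
* **Shear planes z_s** are the first outward crossings of half the bulk
  water density, linearly interpolated between bin centers. "Bulk" is the
  mean over the outermost 20% of |z| (configurable; the choice only
  matters if the water slab is thin).
* **z_m**, the water-layer midpoint, lies halfway between the two shear
  planes measured through the periodic boundary, since after centering the
  water slab is contiguous across z = ±L_z/2.
* **c̄_blk** is the geometric mean of the two ion densities interpolated
  at z_m, converted by 10²⁴/N_A to mol·L⁻¹.

## Ion binding

Bound counts integrate the centered ion density from the bilayer center
z = 0 out to each leaflet's shear plane (trapezoid on bin centers with end
interpolation; at 500-bin resolution the quadrature choice changes results
by <0.1%). The leaflet-wise occupancy α̃ = Ñ_b/(N_L/2) feeds the law of
mass action K_app = α̃/((1−α̃)·c̄_blk); the two leaflets give independent
estimates whose mean and standard deviation are reported. K_int multiplies
by exp(β q_I Δζ) with Δζ supplied by the user — this package does not
estimate zeta potentials from trajectories.

## Mechanics

κ_A uses the population variance of the per-frame area per lipid; it is
only physically meaningful for barostats with correct volume fluctuations,
which is why the pipeline config lets each run name a separate
`kappa_source` twin, and a salt-free `aLo_source` run for the reference
area in P_MD. The two disjoining-pressure routes are deliberately kept
separate: P_MD infers the image–image force from elasticity and the
salt-induced area change; P_TH is the osmotic repulsion k_BT(√ρ_Na−√ρ_Cl)²
from unequal counterion densities at the water midplane. Note the algebra:
substituting P_MD into the finite-size relation
a_L,o,∞ = a_L,o (1 − P d_w/κ_A) returns a_L identically, so the nontrivial
extrapolation is the one driven by P_TH; both entry points are exposed and
the identity is tested rather than hidden.

## Order parameters and hydrogen reconstruction

United-atom tails carry no hydrogens, so C–D unit vectors are rebuilt from
the carbon skeleton. For an sp³ CH₂ at C_i the two deuteriums lie in the
plane spanned by the (unit-bond) angle bisector and the normal of the
C_{i−1}C_iC_{i+1} plane, opening at the tetrahedral H–C–H angle of
109.47°; equivalently they are the bisector rotated by ±54.735° about the
difference of the unit bond vectors, which is the construction the
geometric oracle test uses. An sp² CH gets the single in-plane vector
completing the trigonal arrangement. First (carboxyl) and last (methyl)
carbons of each chain are excluded. The 109.47° convention is an
assumption of this package — published united-atom analyses rarely state
theirs — and the oracle pins our convention, not anyone else's.

S = ⟨3cos²θ−1⟩/2 averages over deuteriums, molecules and frames, with the
bilayer normal fixed to z. Rigid-rod fixtures give the closed form
S = −P₂(cos ψ)/2 for tilt ψ (−0.5 at ψ = 0, 0 for isotropic orientations).

## RDFs and coordination shells

g_ij(r) histograms minimum-image pair distances (default Δr = 0.002 nm)
normalized by 4πr²Δr and ρ_j = N_j/⟨V⟩. For shell boundaries the curve is
smoothed with a centered 5-bin moving average purely for extremum
*detection* (integration always uses the raw g): R1 is the first local
minimum after the first peak; when the post-peak decay never turns up
again, the boundary is taken at the first inflection of the decay and a
`shoulder_flag` is set — solvent-separated binding often erases the first
minimum. N1 and N2 integrate 4πρ_j r² g(r) to R1 and R2 by trapezoid.

## Diffusion

Lateral MSDs average over the lipids of one leaflet and all time origins,
computed with the FFT autocorrelation identity (O(T log T), validated
against the O(T²) double loop). Coordinates are unwrapped by cumulative
minimum-image displacements of the molecular centers of mass; wrapped
input without unwrapping is detected and rejected. Per window (2–6 ns,
100–500 ps, 2–10 ps) the effective D is the least-squares MSD slope over
the window divided by 4, leaflet-averaged, with the error propagated from
the per-leaflet slope standard errors. Because lipid motion is anomalous,
these are *effective*, timescale-dependent coefficients; the package makes
no attempt to fit an anomalous exponent.

## Electrostatics

φ(z) solves the 1D Poisson equation for the binned atom-based charge
density with zero field in the bulk: the field is accumulated at bin edges
by exact suffix bin-sums (for a neutral system the bottom-edge field is
then exactly zero, and mirroring the density exactly mirrors the
potential — a trapezoid on bin centers loses both properties through its
endpoint half-weights), and the piecewise-linear field is integrated
analytically down to each bin center. Component potentials
(all/ions/lipids/water) are anchored to zero in the bulk (mean over the
outermost 10% of |z|) except water, anchored at the bilayer center;
profiles are optionally symmetrized as (φ(z)+φ(−z))/2. Atom-based charge
summation is the common convention for membrane systems even though a
molecule-based multipole bookkeeping would be more rigorous; we follow the
convention and note the caveat rather than "fixing" it.

## Undulation spectrum and Helfrich fit

The displacement field pools the glycerol–tail junction carbons of both
leaflets (per-leaflet mean subtracted) onto a 12×12 periodic grid; empty
cells take the periodic 8-neighbor average, iterated to a fixed point.
With Ũ = FFT2(z̄)/N², a pure mode A·cos(q₀x) carries A²/4 per conjugate
mode and Parseval reads Σ|Ũ_q|² = mean(z̄²); intensities are binned with
one bin per distinct |q| on the lattice (no smoothing), the zero mode
excluded. The fit ⟨u²(q)⟩ = k_BT/(⟨L_x⟩²(k_c q⁴ + γ̃ q²)) is unweighted
nonlinear least squares on u² up to q_max = 2.0 nm⁻¹, with internally
scaled parameters (10⁻²⁰ J, mN·m⁻¹) and an r² computed on fitted vs
observed intensities. The synthetic Helfrich sampler draws complex
Gaussian mode amplitudes (exponential intensities — the equilibrium
distribution of a harmonic mode) under the *same* FFT convention, so the
closure test is convention-independent by construction. Coarse 12×12
gridding of a finer real surface biases high-q intensity low; the closure
therefore validates estimator consistency, not grid-resolution effects.

## Force-field pair tables

Heteroatomic C6/C12 default to geometric means of the homoatomic values.
The calibration scheme overrides exactly three pair groups, C12 only:
Na⁺–Cl⁻ ×1.33; Cl⁻ against the three tail types LP2/LP3/LH1 ×0.057; Na⁺
against *every* lipid type ×3.2 (variant m1) or ×3.0 (m2) — "every lipid
type" read literally as head + glycerol + tails. The Na⁺–Cl⁻ pair is
excluded from the Na⁺–lipid scaling since it carries its own factor.
Tables carry a provenance tag so a scaled table cannot be scaled twice. No
proprietary base parameters ship with the package; tests use a synthetic
toy table, users supply their own.

## Synthetic data: what it does and does not show

Each generator is seeded (bit-reproducible) and emits a JSON manifest of
its ground truth. The bilayer generator draws independent equilibrium
resamples — correct for density-profile and binding stages, but it has no
dynamics, no lipid chemistry and no ion–lipid correlations beyond the
imposed ρ(z) shapes. Its defaults mirror the study conditions of a
128-lipid patch in ~0.5 M NaCl (a_L = 0.542 nm², ⟨L_z⟩ = 9.02 nm,
D_HH = 4.31 nm, 5020 waters, 50 ion pairs); an optional relative area
fluctuation (`box_area_sigma`) mimics barostat volume statistics for the
compressibility stage. The random-walk generator offers normal walks
(variance 2DΔt per dimension), a time-rescaled variant with
MSD(t) = 4Dt^α from the origin (note its increments are non-stationary, so
the all-origin-averaged MSD follows the exact origin-averaged expectation,
which the tests use as oracle), and a stationary two-regime variant —
Ornstein–Uhlenbeck "cage" components superimposed on slow Brownian drift,
MSD(τ) = 4Dτ + Σ 4σ_i²(1−e^{−τ/τ_c,i}) — whose window-fitted effective D
decreases from short to long lags by construction, emulating the
timescale dependence of lipid center-of-mass motion. Passing closures on
these fixtures demonstrates estimator correctness, not force-field or
sampling adequacy on real trajectories.

## Problem sizes

Closure tests run at sizes chosen to put Monte-Carlo noise comfortably
below the asserted tolerances while keeping the suite quick: 2000 frames
of a 12×12 Helfrich grid (k_c recovery well inside 15%), 500 walkers ×
3001 frames at 2 ps for diffusion (10% per window), 2×10⁵ sampled charges
for the Poisson slab (mean curvature within 1%), and 10⁴–10⁵ draws for
order-parameter and block-averaging statistics.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* D_HH from raw bin maxima is noisy for broad phosphorus peaks; at 500
  bins a jitter of one or two bins (~0.02–0.04 nm) is expected.
* The block-average "maximum over block counts" heuristic can over-report
  errors by tens of percent for short, weakly correlated series.
* κ_A from area fluctuations inherits any barostat artifacts of the input
  trajectory; the package cannot detect these.
* The Helfrich fit treats binned intensities as homoscedastic; for
  strongly tensed membranes a weighted or log-space fit would be more
  efficient (not implemented).
* No electron-density or X-ray form-factor profiles, no Poisson–Boltzmann
  solving, no zeta-potential estimation, no rotational diffusion.
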