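# Methods

This note documents the models and estimators implemented in `toxmem`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices that
matter for reproducing the outputs.

## Units

Internal units are nm, ns, elementary charge e and Da. Diffusion
coefficients cross the module boundary in cm²/s (1 nm²/ns = 10⁻⁵ cm²/s),
dipoles in Debye (1 e·Å = 4.80320 D), energies in kcal/mol with
kB = 0.0019872041 kcal/(mol·K). Mixing Å, nm and cm²/s inside the code is
the classic source of silent errors in this kind of analysis; all
conversions live in `toxmem.units`.

## Insertion scoring

The head-group surface of the toxin-proximal (upper) leaflet is modelled per
frame as a least-squares plane z = a·x + b·y + c through that leaflet's head
COMs only. Fitting both leaflets would put the reference at the bilayer
midplane and misclassify shallow insertions as non-events, so only the
contacted leaflet enters the fit; the lower leaflet is fitted separately
when asked for. A residue is inserted in a frame when its reference z lies
*strictly below* the surface evaluated at its (x, y). Three reference
conventions are supported: residue COM (default), side-chain COM (drops the
backbone contribution), and a below-C1 variant that compares against the
mean z of the upper-leaflet acyl C1 carbons — a horizontal plane, since no
per-lipid fit is meaningful for a single carbon per lipid. With the C1 plane
below the head plane the below-C1 events are a subset of the residue-COM
events for coinciding reference points.

Counting is gated: no insertion is scored before the first frame in which
the toxin COM is strictly closer than 0.5 nm (configurable) above the fitted
surface. The gate removes incidental collisional contacts during the
approach. The comparison is strict; a distance of exactly 0.5 nm is not a
contact. If the gate is never satisfied the insertion matrix is all-False
and a warning is emitted rather than an error, because "never bound" is a
legitimate outcome of a binding simulation.

Ip is the inserted fraction of frames in an analysis window; the default
window runs from the COM-distance plateau (detected by requiring the
moving-window OLS slope of the toxin-to-membrane-COM distance to stay below
a tolerance, default 10⁻³ nm/ns over 10-frame windows) to the end of the
trajectory, and the window may never start before the gate onset —
pre-contact frames appear in neither numerator nor denominator. IS sums Ip
over residues, so IS of a merged window is the frame-weighted mean of
sub-window IS values (tested). The IS time derivative lays non-overlapping
windows (default 500 ns) from the onset and reports the OLS slope of window
IS against window midpoint time, in IS units per μs.

Membrane descriptors are the standard ones: area per lipid = lateral box
area / lipids per leaflet (per leaflet and averaged), thickness = mean upper
head z − mean lower head z, and axial number densities normalized per frame
and per bin volume so the profile integrates to the mean particle count.

## Dipole analysis

The molecular dipole of a net-charged peptide depends on the reference
point: shifting the origin by Δ changes μ by −q_net·Δ. The package uses the
mass-weighted COM — the common MD convention — and exposes the origin as an
argument plus a tested statement of the shift law instead of hiding the
dependence. Angles are measured from +z (the outward membrane normal
through the upper leaflet) on [0°, 180°] and are undefined below a magnitude
tolerance of 10⁻⁶ D. Angle histograms are normalized to unit mass;
solid-angle (1/sin θ) weighting is available and off by default, because the
raw distribution is what orientation plots in the field usually show. No
smoothing is applied to magnitude series.

## Diffusion

MSD uses every frame as a time origin (stride configurable). For unit
stride the curve is computed with the FFT autocorrelation identity, which
is algebraically identical to the brute-force double loop (tested to
10⁻¹⁰ on small inputs) at O(N log N) cost. Coordinates must be unwrapped;
a jump larger than half a box length trips an explicit error pointing at
the `unwrap` utility.

The Einstein fit regresses MSD on lag over a window given as fractions of
the maximum lag, default 10–50%, and converts the slope via D = m/(2d). For
*validation against Brownian ground truth* the analyses restrict the curve
to `max_lag_fraction = 0.002` of the trajectory before fitting: the
relative sampling variance of an all-origins MSD estimate grows roughly as
2m/(3N) with lag m, so for an ideal random walk (no short-lag registration
artifacts to avoid) the shortest lags carry essentially all the
information. At 2×10⁵ steps this keeps the estimator's relative error a few
percent. The recovery analyses use 2×10⁵-step walks as a problem size that
makes this sampling error comfortably small at desk-scale runtime.

The finite-size correction implements the periodic Saffman–Delbrück
picture: a membrane inclusion in a periodic box of lateral size L
underestimates the infinite-system lateral D by an amount that grows
logarithmically as L shrinks below the Saffman–Delbrück length
L_SD = η_m/(2η_w) (η_m the membrane *surface* viscosity in Pa·s·m, η_w the
bulk viscosity). The implemented correction is the interpolating form

    Δ(L) = kBT/(4π η_m) · ln(1 + L_SD/L),

which matches the small-box logarithmic asymptote and vanishes as L → ∞,
is non-negative and strictly decreasing in L, with every physical parameter
explicit (defaults: η_m = 5×10⁻¹⁰ Pa·s·m, η_w = 10⁻³ Pa·s, T = 298 K,
L = 16 nm). It is a smooth bridge between the two proven limits rather than
the full Ewald-style lattice sum, so only its limit and monotonicity
behaviour — not digit-level agreement with any particular lattice-sum
implementation — is asserted in tests.

## Well-tempered metadynamics

The engine is deliberately 1D: the collective variable is a scalar, hills
are exact Gaussians (no grid splines), and dynamics are overdamped Langevin
(x ← x + (F/γ)dt + √(2kBT dt/γ)·ξ) so that every moving part is testable
against closed forms. Tempering follows the standard rule: each deposited
hill has height W₀·exp(−V(x)/kBΔT) with V the bias accumulated at the
deposition point, so heights are positive, bounded by W₀, and constant in
the ΔT → ∞ limit (untempered metadynamics, tested at ΔT = 10⁹ K). Soft
harmonic walls (default force constant 10 kcal/mol per CV-unit², matching
the restraint constants used elsewhere in the workflow) confine sampling.
The PMF estimator is −(T+ΔT)/ΔT·V + C with C fixing the grid minimum to 0;
for T = 298 K and ΔT = 1500 K the scale is 1.19867. A time-averaged variant
averages the instantaneous estimate over the last half of the hill history,
which suppresses the residual oscillation of a still-growing bias and is
the estimator used for barrier readouts.

Convergence benchmark: a symmetric double well U = b((x/a)² − 1)² with
b = 3 kcal/mol, a = 1, walls at ±1.6, W₀ = 0.5 kcal/mol, width 0.1,
ΔT = 1500 K, deposition every 200 steps, dt = 5×10⁻³, 10⁶ steps. The
recovered barrier sits within 0.2 kcal/mol of the analytic value across
seeds (asserted at 0.3). The inner loop is JIT-compiled with hill
evaluation truncated beyond 8 Gaussian widths (exp(−32) ≈ 10⁻¹⁴, far below
any asserted tolerance).

The membrane system's orientational/conformational restraints and its
actual desorption PMF are out of scope here: the engine demonstrates the
machinery on analytic potentials where the truth is known.

## Block averaging and energy decomposition

Block averaging computes the SEM of block means for doubling block sizes
while at least 8 blocks remain. The SEM(b) curve is fitted with
s(b) = s∞(1 − e^(−b/b0)) + s(1)·e^(−b/b0), each point weighted by the
sampling error of a SEM estimate, sem/√(2(n_blocks − 1)) — without the
weights the fit is degenerate for uncorrelated data (b0 → ∞ at unbounded
s∞). s∞ is the reported error; (s∞/s(1))² is the statistical inefficiency,
which for an AR(1) process with lag-1 autocorrelation φ has the closed form
(1+φ)/(1−φ) used as the test oracle.

The decomposition consumes per-frame pair-energy tables over a closed label
vocabulary (four toxin-involving pairs, six rest pairs) plus per-frame
totals, and reports Δ = mean(bound) − mean(unbound) for ToxVdW, ToxEle,
RestVdW, RestEle and the four totals, each with the two block-average
errors combined in quadrature. Restraint energies are excluded from the
bookkeeping by construction. Category sums reproduce totals exactly on
consistent inputs (partition identity, tested to 10⁻⁹).

## Reduction-of-dimensionality model

F₂ is the equilibrium fraction of receptor-binding rate arriving via the
membrane-bound 2D pathway for a reaction-limited, reversibly adsorbing
ligand; the model's assumptions (indirect 2D/3D coupling through reversible
adsorption, equally accessible randomly placed binding sites, low binding
probability per collision, single occupancy, spherical geometry,
equilibrium concentrations) are taken as given, not relaxed. The Brownian
persistence distances σ and collision-success fractions χ enter only
through the ratios σ₂/σ₃ and χ₃/χ₂, both defaulting to 1. The capture
radius is accepted in nm (default 0.5) and converted to cm internally;
SA:V defaults to 10⁶ cm⁻¹ (a microscale spherical compartment), D₃ to the
measured bulk value 1.0×10⁻⁶ cm²/s and D₂ to the measured lateral value
4.1×10⁻⁸ cm²/s. With these defaults F₂(Kp=1) = 0.582, F₂ is strictly
increasing in Kp and D₂, and reducing D₂ to 10⁻⁹/10⁻¹⁰ cm²/s shifts the
half-saturation Kp right by roughly the same factor.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical geometry* the estimators consume,
not membrane physics. Bilayers are planar leaflets at ±2 nm with Gaussian
head roughness (default σ = 0.05 nm) on a jittered lattice; defaults follow
the reference all-atom construction (11.5 × 11.5 nm, 308 lipids, POPG
fraction by composition, e.g. 231:77 at 3:1). The POPG count is
round-half-away-from-zero of fraction × n_lipids, split evenly with an odd
remainder to the upper leaflet — a documented deterministic rule. Binding
trajectories descend rigidly from 2.5 nm (the all-atom starting distance)
to the 0.5 nm gate at a prescribed onset frame, then fluctuate about
prescribed per-residue depths; the ground-truth insertion matrix is
attached at generation time. Brownian walks draw i.i.d. Gaussian increments
of variance 2·D·dt per dimension; AR(1) series are initialized from their
stationary distribution.

None of this contains force fields, lipid–peptide interactions, wrapping,
or hydrodynamics. Passing tests therefore demonstrate that the estimators
are correct on data whose generating process is known exactly — they do not
validate force-field choices or sampling adequacy of any real simulation.
Real-trajectory concerns handled only minimally: periodic unwrapping is
provided as an explicit utility with a trip-wire in the MSD code, and the
canonical long-format CSV container is the interchange format (GRO+XTC /
PDB+DCD adapters are out of scope).

Every generator is a pure function of its spec with an independently seeded
stream, so adding a call cannot shift another generator's output, and equal
seeds give bitwise-equal arrays.

## Degenerate inputs and tie-breaks

Plane fits require ≥ 3 non-collinear heads (rank check, explicit error).
Insertion comparisons are strict inequalities throughout, so points exactly
on a surface are not inserted and distances exactly at the gate are not
contacts. Empty or pre-onset Ip windows are errors; a never-gated
trajectory yields all-zero Ip with a warning. Zero-magnitude dipoles have
no angle (tolerance 10⁻⁶ D). The metadynamics integrator raises with the
step index when a step diverges. `block_error` needs ≥ 16 samples and falls
back to the tail mean of SEM(b) if the plateau fit fails to converge.

## Known limitations

- The PSD correction is an asymptotic interpolation (see above), suitable
  for order-of-magnitude finite-size reasoning, not lattice-sum-exact.
- The metadynamics engine is 1D and overdamped by design; no multi-CV,
  replica or reweighting machinery.
- The Ip denominator counts all post-onset (or explicit-window) frames;
  alternative conventions are reachable through the window argument.
- Synthetic binding trajectories have no lateral peptide diffusion and no
  membrane deformation; lateral motion is modelled separately by the
  Brownian generator where diffusion is the quantity under test.
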