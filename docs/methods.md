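# Methods

This note records the models implemented in `hostguest`, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Equilibrium models

The 1:1 host–indicator system is governed by the association quadratic in
the complex concentration; the physically admissible root is the smaller
one, computed in the "citardauq" form 2c/(b + √(b²−4c)) so that weak
binding (c ≪ b²) does not lose precision to cancellation. K = 0 returns
no complex; K = +∞ is accepted as the stoichiometric limit
[HI] = min([H]ᵀ, [I]ᵀ).

The competitive (indicator-displacement) system couples two binding
equilibria through three mass balances. Eliminating the free indicator
and free competitor through their isotherms leaves one equation in the
free host concentration h,

    h + K₁h[I]ᵀ/(1+K₁h) + K₂h[G]ᵀ/(1+K₂h) = [H]ᵀ,

whose left side is strictly increasing in h, so a bracketed Brent solve on
[0, [H]ᵀ] is globally convergent. The closed cubic polynomial sometimes
quoted for this system is not used: the mass-balance root-find encodes the
same physics without relying on a transcribed polynomial, and the solution
is validated in the tests against an independent damped fixed-point
iteration on the free concentrations (10³–10⁴ random parameter draws,
agreement to 1 part in 10¹⁰).

### Binding-constant fits

Fits work on log₁₀K, which makes the optimizer scale-free across the
10³–10⁹ M⁻¹ range typical of macrocyclic hosts. The spectroscopic response
is linear in the free indicator and the complex (the free dye retains
residual emission, so a pure "signal ∝ [HI]" model is offered only as an
option); because both coefficients enter linearly they are profiled out
exactly at each trial K by linear least squares, leaving a 1-D bounded
minimisation multi-started from 10³, 10⁵ and 10⁷ M⁻¹. Displacement fits
hold K₁ fixed (taken from a direct titration) and estimate K₂ through the
exact competitive speciation at every titration point.

Uncertainty is a residual-bootstrap percentile interval (default 500
resamples; the seed is a mandatory argument and is recorded in the fit
object) — chosen because instrument-software "±" conventions vary and a
bootstrap makes the procedure explicit. A constant signal raises an
identifiability error rather than returning an arbitrary K; a competitor
sweep that leaves the complex concentration unchanged (< 0.1% span) does
the same for K₂.

Concentrations are molar everywhere inside the library; the CSV reader
converts from μM when the file declares it.

Thermodynamic bookkeeping uses R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298 K by default; `ThermoRecord` enforces ΔG = ΔH − TΔS to
0.05 kcal/mol when all three are supplied.

## Photophysics

Quantum yields follow the relative slope method against a reference
standard (for quinine sulfate in 0.5 M H₂SO₄, φ = 0.55): the slope of
integrated emission versus absorbance, fitted through the origin by
default, enters φ = φᵣ·(grad_s/grad_r)·(n_s²/n_r²). The refractive-index
correction defaults to n_s = n_r since same-solvent comparisons are the
common case; a computed yield above 1 is returned but warned about.

TCSPC decays are modelled as the discrete convolution of
Σᵢ aᵢ exp(−t/τᵢ) (sampled at bin centres) with the unit-normalised IRF
histogram, plus a flat background. The IRF time offset is a fitted
continuous parameter realised by linear interpolation of the IRF onto
shifted bins. The objective is Poisson-weighted least squares with weights
1/√max(counts, 1) — standard TCSPC practice, stable at the 10⁴-count scale
this package targets; an exact Poisson MLE objective was considered and
left out as it changes estimates negligibly at these counts. The number
of components is user-chosen (1–3) and the reduced chi-square is reported
for comparison rather than auto-selecting; nearly degenerate fitted
lifetimes (within 5%) trigger an identifiability warning. The optimizer is
a bounded trust-region least-squares solver; the MINPACK
Levenberg–Marquardt variant with transformed bounds proved prone to
stalling far from the optimum on two-component problems and is not used.
Multi-start initial lifetimes derive from the mean photon arrival time,
with seeded perturbations on retry.

## Spectral convolution

Each excitation contributes a Gaussian band
ε(ν′) = (2.175×10⁸/Δν′₁⁄₂)·f·exp(−2.772(ν′−ν′ᵢ→f)²/Δν′₁⁄₂²) in
M⁻¹ cm⁻¹ with wavenumbers in cm⁻¹. The literal constants 2.175×10⁸ and
2.772 (≈ 4 ln 2) are used exactly as conventionally printed, not re-derived
at higher precision, so that output matches the established convolution
convention; the self-consistency Σf = ∫ε dν′/(1.0645×2.175×10⁸) is a
tested invariant. Default band width 3000 cm⁻¹; default grid
10,000–50,000 cm⁻¹ at 10 cm⁻¹, with nm views resampled only at output.
Unit conversions use ν′ = 10⁷/λ and E = 1239.842/λ. The oscillator
strength–dipole relation is the atomic-unit length-gauge identity
f = (2/3)ΔE|M|² (prefactor-free), which is dimensionally consistent with
the broadening constant above. Ensemble statistics report per-snapshot
band maxima of the convolved in-window excitations with the population
(ddof = 0) standard deviation.

## Density topology

The density source is a deliberately minimal wavefunction model: molecular
orbitals over s-type Gaussian primitives with occupation numbers, which
keeps ρ and all derivatives analytic while exercising every piece of the
QTAIM machinery. The four packaged fixtures (one-center, symmetric dimer,
asymmetric dimer, noncovalent dimer) are synthetic constructions, not
electronic-structure outputs; the noncovalent dimer is built so its
intermolecular (3,−1) critical point lies in the closed-shell regime
(∇²ρ > 0, H > 0, −G/V > 1, ρ ≈ 0.012 e·a₀⁻³). Performing QTAIM on a real
host-guest DFT wavefunction is out of scope — those descriptors are
outputs of external engines.

G(r) = ½Σηᵢ|∇φᵢ|² uses the occupied orbitals of the single-determinant
model; V comes from the local virial relation V = ¼∇²ρ − 2G, so H = G + V
holds by construction and the analytic derivatives are verified against
central finite differences (step 10⁻⁴ bohr) in the tests.

Critical-point search: damped Newton on ∇ρ (step halving while the
gradient norm does not decrease, up to 30 halvings; 100 iterations;
gradient tolerance 10⁻¹⁰), seeded from bond midpoints only, since bonded
contacts are what get analysed; converged points within 10⁻⁴ bohr merge;
signatures use a 10⁻¹⁰ eigenvalue zero-threshold, and rank-deficient
Hessians flag the point degenerate rather than raising. Non-convergence
for a pair records an absent point, not an error.

The H-bond energy estimate B_E = −223.08ρ + 0.7423 kcal/mol is a literature
linear calibration for hydrogen-bonded contacts; inputs outside
0.002–0.04 e·a₀⁻³ warn as extrapolation.

NCI grids store the reduced density gradient with voxels above the
ρ ≤ 0.05 e·a₀⁻³ envelope masked, and sign(λ₂)ρ clamped to (−0.05, 0.01)
for export — the standard blue-to-red attractive/repulsive colour range.
Since quoted RDG isovalues vary (0.3–0.7), the isovalue is left to the
visualiser; the default suggestion is 0.5. Atomic units are used
internally; Å↔bohr (0.529177210903) conversion happens only at I/O.

## Solvation analysis

All distances use the minimum-image convention in orthorhombic boxes;
non-orthorhombic cells are out of scope. RDFs are pair histograms
normalised by the ideal-gas shell expectation; first-shell extrema are
read from a 3-point moving average of g(r) (raw-g option available) to
suppress single-bin noise, and the coordination number integrates
4πρ_B g(r)r² to the first minimum by the trapezoid rule.

The hydrogen-bond criterion is geometric: acceptor–donor distance ≤ 3.5 Å
and angle ≤ 30°. The angle's vertex is not fixed by convention in all
tools; here it defaults to the donor, between the D→A and D→H directions,
so that ≤ 30° selects near-linear D–H···A arrangements, with a
vertex-at-hydrogen alternative (deviation from linearity) switchable in
`HBondCriteria`.

Nanodroplet extraction retains waters whose centre of mass (O 15.999,
H 1.008) lies within the cutoff radius (default 20 Å) of the *unweighted*
geometric centre of the solute selection — the centre convention follows
the usual phrasing "geometrical centre of the solute"; distance to the
nearest solute atom would be the main alternative and is not implemented.
Retained waters hydrogen-bonded to the solute in either donor direction
form the QM set, the rest the MM set; the two sets partition the retained
waters exactly.

## Synthetic generators

Generators are pure functions of (parameters, seed) via numpy's
`default_rng`. Fluorescence intensities carry multiplicative Gaussian
noise (the shot-dominated approximation at high photon flux); photon
counting is Poisson. Default regimes mirror a cucurbit[7]uril-type study:
K ≈ 4.5×10⁵ M⁻¹ (direct) and 5.5×10⁵ M⁻¹ (competitor), indicator ~1 μM,
host swept 0–90 μM, competitor 8–1500 μM (log-spaced), decays with 10,000
peak counts and a 0.2 ns FWHM Gaussian IRF over a 40 ns window (25 ps
bins), excitation jitter σλ = 6 nm. These are configuration defaults, not
hard-coded constants.

The solvation generator plants waters at prescribed distance/angle from a
minimal N–H solute (on-axis placements within 3.5 Å satisfy the H-bond
criterion; misangled or distant placements violate it), fills the box with
uniformly placed waters under 2.5 Å overlap rejection while keeping bulk
water out of the 4 Å planted-shell region, and jitters frames by
σ = 0.02 Å. It emulates *planted structure only*: there are no realistic
water–water correlations, polarisation or dynamics, so passing solvation
tests demonstrates the correctness of the estimators (histogramming,
geometry, partitioning), not agreement with real hydration structure —
reproducing experimental RDF peak positions would require a real MD
trajectory, which this package consumes but does not produce.

The same caveat applies package-wide: generator/analyzer round trips show
that each fit recovers what was planted under the stated noise model, not
that real instruments obey that noise model.

## Problem sizes and tolerances in the test suite

Oracle comparisons run 10⁴ (1:1, vectorised bisection) and 10³
(competitive, damped fixed point) random draws at 10⁻¹⁰ relative
agreement. Fit-recovery checks span K = 10³–10⁹ M⁻¹ noiseless (< 0.5%)
and seeded noisy series (< 5% direct, < 10% displacement). Lifetime
recovery uses 50 seeded replicates at 10,000 peak counts (bias < 1%,
RMSE < 3%). Electron-count quadrature uses a 120³ grid over ±7–10 bohr
(0.1% tolerance). These sizes keep the full suite under a minute of
numerics on one CPU while leaving each tolerance comfortably bounded away
from the observed error.

## Known limitations

- Only 1:1 and 1:1:1 competitive stoichiometries; no global
  multi-wavelength fitting; no ITC power-curve (Wiseman) fitting.
- Wavefunction models are restricted to s-type primitives; no basin
  integration, ELF, or Hirshfeld surfaces.
- No anisotropy or global lifetime analysis; no instrument artifacts
  (afterpulsing, pile-up) in the decay generator.
- Orthorhombic boxes only; water topologies are rigid three-site.
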