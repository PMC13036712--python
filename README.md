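# hostguest

Analysis toolkit for supramolecular indicator-displacement sensing studies:
the kind of experiment where a fluorescent dye binds inside a macrocyclic
host (for instance a cucurbit[7]uril cavity), its photophysics change on
inclusion, and an analyte is then quantified by competitively displacing
the dye. The package covers the full data-analysis chain of such a study —
equilibrium fitting, photophysics, spectral modelling, electron-density
topology and solvation statistics — together with seeded synthetic-data
generators so every stage can be exercised and validated without any
instrument or external electronic-structure output.

## What it computes

**Binding equilibria** (`hostguest.equilibria`). For a 1:1 host–indicator
titration the complex concentration is the physical root of

    [HI]² − ([H]ᵀ + [I]ᵀ + 1/K₁)[HI] + [H]ᵀ[I]ᵀ = 0,

and for the competitive system H + I ⇌ HI (K₁), H + G ⇌ HG (K₂) the exact
three-species mass balance is reduced to a monotone scalar equation in the
free host concentration and solved with Brent's method. Binding constants
are fitted on a log₁₀K scale with the linear response model
I = a·[I]ₗᵣₑₑ + b·[HI] profiled out exactly, multi-start at 10³/10⁵/10⁷ M⁻¹,
and a residual-bootstrap 95% interval. ΔG = −RT ln K and ΔG = ΔH − TΔS
bookkeeping round out the thermodynamics.

**Photophysics** (`hostguest.photophysics`). Relative quantum yields by the
reference-slope method, φ = φᵣ·(grad_s/grad_r)·(n_s²/n_r²), and fluorescence
lifetimes by iterative reconvolution of a multi-exponential decay with the
measured instrument response function (Poisson-weighted least squares,
fitted sub-bin IRF shift, fractional intensities fᵢ = aᵢτᵢ/Σaⱼτⱼ).

**Spectra** (`hostguest.spectra`). Gaussian convolution of computed
excitation tables into molar absorptivity,
ε(ν′) = (2.175×10⁸/Δν′₁⁄₂)·f·exp(−2.772(ν′−ν′ᵢ₋ₓ)²/Δν′₁⁄₂²), default band
width 3000 cm⁻¹; nm/cm⁻¹/eV conversions; oscillator-strength ↔ transition-
dipole identity f = (2/3)ΔE|M|²; snapshot-ensemble λmax statistics; and
Beer–Lambert ε fits.

**Density topology** (`hostguest.density_topology`). QTAIM descriptors
(ρ, ∇ρ, ∇²ρ, G, V = ¼∇²ρ − 2G, H = G + V) evaluated analytically from a
minimal Gaussian-primitive wavefunction model; Newton search for (3,−1)
bond critical points; closed-shell classification (∇²ρ > 0, H > 0,
−G/V > 1); the linear H-bond energy estimate B_E = −223.08ρ + 0.7423
kcal/mol; and NCI grids of the reduced density gradient
s = |∇ρ|/(2(3π²)^⅓ρ^4/3) against sign(λ₂)ρ, exported as cube files.

**Solvation** (`hostguest.solvation`). Minimum-image radial distribution
functions with first-shell coordination numbers, geometric hydrogen-bond
detection (acceptor–donor ≤ 3.5 Å, angle ≤ 30°), extraction of a spherical
nanodroplet of waters around a solute with the H-bonded subset tagged for
QM treatment, and 3D occupancy maps.

**Synthetic data** (`hostguest.synthetic`). Seeded generators for every
input: noisy 1:1 and displacement titrations, Poisson TCSPC traces with
Gaussian IRF smearing, jittered excitation ensembles, and water boxes with
planted solvation shells.

## Worked example

```python
from hostguest.synthetic import gen_titration, gen_decay
from hostguest.equilibria import fit_1to1, gibbs_from_k
from hostguest.photophysics import fit_reconvolution

# a 16-point host titration (0-90 uM host, 1 uM dye), 1% multiplicative noise
series = gen_titration(K=4.54e5, noise_sd=0.01, seed=42)
fit = fit_1to1(series, n_boot=200, seed=0)
print(f"K  = {fit.K_hat:.3g} M^-1  (95% bootstrap CI "
      f"{fit.K_interval[0]:.3g} - {fit.K_interval[1]:.3g})")
print(f"dG = {gibbs_from_k(fit.K_hat):.2f} kcal/mol")

# a two-component decay at 10,000 peak counts, 0.2 ns IRF
trace = gen_decay(lifetimes=(0.59, 4.87), fractions=(0.04, 0.96), seed=5)
res = fit_reconvolution(trace, n_components=2, seed=0)
print(f"tau = {res.model.lifetimes[0]:.2f}, {res.model.lifetimes[1]:.2f} ns")
print(f"fractional intensities = {res.fractional_intensities[0]:.1f}%, "
      f"{res.fractional_intensities[1]:.1f}%")
```

prints

```
K  = 4.39e+05 M^-1  (95% bootstrap CI 4.04e+05 - 4.72e+05)
dG = -7.69 kcal/mol
tau = 0.55, 4.84 ns
fractional intensities = 3.9%, 96.1%
```

The fitted K sits within the bootstrap interval of the generating
4.54×10⁵ M⁻¹; the long lifetime and its ~96% contribution recover the
planted decay structure through the IRF.

A command-line interface mirrors the library
(`hostguest fit-binding | fit-ida | lifetime | qy | spectrum | nci | cps |
rdf | hbonds | droplet | density-map | simulate`); `simulate` writes the
same file dialects the analysis commands read, so a full round trip is:

```sh
hostguest simulate titration --seed 5 --out tit.csv
hostguest fit-binding tit.csv --n-boot 200 --seed 1 --out fit.json
```

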