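# Methods

## Model

All energies are Gibbs energies in kcal/mol at T = 298.15 K unless stated;
physical constants are CODATA-2018 (`radkin.constants`).

### Speciation

For an n-protic acid with stepwise constants pKa₁ ≤ … ≤ pKaₙ, the mole
fraction of the j-times-deprotonated state at a given pH is

    f_j ∝ 10^(j·pH − Σ_{i≤j} pKa_i),

normalized over j = 0…n. The largest exponent is subtracted before
exponentiation so extreme pH/pKa combinations cannot overflow. When pKa
values are not given directly they are derived from the deprotonation Gibbs
energy in solution via

    pKa = ΔG_sol/(RT·ln10) + 14 + 3·log₁₀([H₂O]),   [H₂O] = 55.345 M,

the standard-state correction for a reaction written against liquid water.
States with fraction below 10⁻³ are dropped from kinetics. In non-aqueous
media only the neutral state is populated and SET channels are skipped.

### Screening

Channels are classified by reaction Gibbs energy ΔG⁰: favorable (ΔG⁰ ≤ 0),
borderline (0 < ΔG⁰ ≤ cutoff, default 5 kcal/mol, retained because thermal
corrections and tunneling can still make such channels competitive), excluded
otherwise. Channels without a ΔG⁰ are retained by assumption and flagged.

### Rate constants

HAT and RAF channels use conventional transition-state theory,

    k = σ·κ·(k_B T/h)·exp(−ΔG≠/RT),

with reaction-path symmetry number σ (default 1) and tunneling correction κ.
κ may be supplied directly or computed from an asymmetric Eckart barrier
(forward barrier V₁, reverse barrier V₂, imaginary wavenumber ν̃):

    κ(T) = β e^{βV₁} ∫₀^∞ p(E) e^{−βE} dE,

where p(E) is the closed-form Eckart transmission probability. p(E) = 0 below
the product asymptote (E < V₁ − V₂); for barriers too thin for the bound-state
parameter (α₁α₂ ≤ π²/4) a classical step function is used.

SET channels use Marcus theory,

    ΔG≠ = (λ/4)(1 + ΔG⁰/λ)²,

with κ = 1. The reorganization energy λ is taken directly or rebuilt as
λ = ΔE_SET − ΔG⁰_SET from the vertical and adiabatic energies.

### Diffusion correction and aggregation

Every activation-controlled rate is corrected with Collins–Kimball,

    k_app = k_act·k_D / (k_act + k_D),

where the encounter rate k_D comes from Smoluchowski,
k_D = 4π(r_A+r_B)(D_A+D_B)N_A·10³, with Stokes–Einstein diffusivities
D = k_B T/(6πηr). Channel rates are population-weighted (k_f = f·k_app),
summed to k_overall, and reported with branching ratios
Γ_i = 100·k_f,i / k_overall.

## Parameter defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| Temperature | 298.15 K | standard conditions of the study fixtures |
| pH (aqueous) | 7.4 | physiological |
| Borderline cutoff | 5 kcal/mol | endergonic channels below this can still contribute after tunneling |
| Negligible fraction | 10⁻³ | states below 0.1% cannot move a 3-significant-figure k_overall |
| Water viscosity | 8.91·10⁻⁴ Pa·s | 25 °C literature value |
| Pentyl ethanoate viscosity | 8.62·10⁻⁴ Pa·s | 25 °C literature value |
| Aqueous k_D | 2.30·10⁹ M⁻¹s⁻¹ | calibrated default (below) |

The calibrated aqueous k_D deserves a note: for any physically plausible
radii, Stokes–Einstein + Smoluchowski in water cannot go below ≈7.4·10⁹
M⁻¹s⁻¹ (the equal-radii minimum is radius-independent). The study fixtures
use 2.30·10⁹, which therefore must encode reactive-distance and orientational
effects beyond the bare hydrodynamic model. It is kept as an explicit default
override, not back-fitted to radii. A medium may instead give an explicit
`diffusion_override` or radii + viscosity (the hydrodynamic route).

## Numerical choices

- **Eckart quadrature.** The thermal average is integrated in ε = E − V₁ over
  [−V₁, 20RT] with adaptive quadrature. The transmission function has a
  boundary layer of width w = hcν̃/2π around the barrier top that a naive
  adaptive pass can step over for small ν̃; the integral is therefore split at
  ±5w and ±50w (and at the product asymptote), with epsabs = 10⁻¹⁴,
  epsrel = 10⁻¹⁰. An estimated error above 10⁻⁶·κ raises `ArithmeticError`
  rather than returning a silently degraded value. The adaptive path agrees
  with a 10⁶-point brute-force trapezoid oracle to better than 10⁻⁴ relative
  over random barriers (V ∈ [2, 15] kcal/mol, ν̃ ∈ [800, 2200] cm⁻¹).
- **cosh ratios** in the transmission probability are evaluated as
  exponential-difference forms with argument clipping, stable to V ≈ 700 in
  reduced units.
- **λ convention.** The reorganization energy is reconstructed as the
  *difference* ΔE_SET − ΔG⁰_SET; this is the only convention consistent with
  the fixture values (8.8 − 4.8 = 4.0 and 4.03 − 2.93 = 1.1 kcal/mol).
- **Determinism.** All report writers sort keys and fix float formats, so
  equal inputs give byte-identical files.

## Synthetic generator

`radkin.synthetic.generate_scenario(seed, n_states, n_pathways, regime)`
draws a polyprotic compound (pKa ~ U(3, 11)), channel thermochemistry
(ΔG⁰ ~ U(−15, 45)), and per-regime kinetic descriptors:
`activation_controlled` (ΔG≠ ~ U(2, 20)), `diffusion_limited`
(ΔG≠ ~ U(0.5, 4)), or `mixed`; supplied κ = 10^U(0,3); SET channels with
λ ~ U(1, 20); k_D = 10^U(9,10). Scenarios carry supplied tunneling factors so
the ground truth — computed by an independent straight-line implementation
with its own constants and Henderson–Hasselbalch fractions — is exact;
`recover_parameters` demands agreement with the pipeline to 10⁻⁹ relative,
plus a 3-significant-figure serialization round trip. The Eckart integrator
is validated separately against the brute-force oracle because adaptive
quadrature is only certified to ~4 significant figures. Generator defaults
are study conditions and are exercised as-is by the tests.

## Limitations

- Inputs are curated thermochemical descriptors; the package does not parse
  electronic-structure program output.
- The Eckart correction assumes a one-dimensional separable reaction
  coordinate; multidimensional or corner-cutting tunneling is out of scope.
- Marcus rates use κ = 1 (adiabatic limit); no electronic-coupling model.
- The screening step is a Gibbs-energy gate only; it does not anticipate
  channels rescued by very large tunneling factors.
- Several printed rows of the shipped study tables are internally
  inconsistent with their own (ΔG≠, κ) descriptors; they are preserved
  verbatim in supplied-rate mode, flagged in the fixture notes, and excluded
  from computed-mode cross-checks.
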