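# Methods

## Model and assumptions

The trait is additive over a very large mutational target: an individual's
value is the sum of the effects of the alleles it carries at `L >> 1` freely
recombining biallelic sites, and fitness is Gaussian in the trait,
`W(z) = exp(-z²/(2V_S))`. The population is diploid, panmictic, of constant
size `N`, with non-overlapping generations (Wright–Fisher sampling with
fertility selection). Mutation follows the infinite-sites approximation:
Poisson(`U`) new trait-affecting mutations per gamete per generation, with
effects `±a` symmetric in sign and squared magnitudes `S = a²` drawn from a
distribution `g`. An additive environmental contribution is not modeled
explicitly: it is absorbed into `V_S` (the individual-based engine can add
Gaussian noise to the selected phenotype for demonstration, but recorded
moments are always genetic).

The analytic results assume the regime in which the trait is highly
polygenic and selection per site is weak:

| assumption | check |
|---|---|
| high polygenicity | `2NU >> 1` (warn at `2NU <= 1`) |
| modest genetic load | `U <= 0.02` |
| weak selection per allele | bulk of `g` has `a << sqrt(V_S)` |
| meaningful but moderate shift | `δ < Λ <~ sqrt(V_S)` |
| small per-site frequency changes | `Λ/sqrt(V_A(0)) <~ sqrt(2NU)/2` |

`validate_assumptions` warns rather than errors on violations, so the
regimes outside the theory's domain remain explorable; every warning is also
returned as a value. Note that the canonical "Lande" study conditions
(`U = 0.03`) intentionally sit slightly above the load bound and are flagged.

## Units

All internal computation uses δ units: the trait is measured in units of
`δ = sqrt(V_S/2N)`, the standard deviation of the equilibrium fluctuations
of the mean phenotype around the optimum. Then `V_S = 2N`, an allele of
magnitude `a` has population-scaled selection coefficient `S = 2N·s_e = a²`,
and all per-unit-input results are invariant to `N` and `V_S` separately.
Raw-unit parameters are converted on ingestion (`ModelParams.to_delta_units`).

## Equilibrium architecture

For minor allele frequency `x ∈ (1/2N, 1/2]` and magnitude `a` (δ units),
per unit mutational input:

- `ℓ(a,x) = 2·exp(-a²x(1-x))/(x(1-x))` — expected site density. This is the
  sojourn-time density of the Wright–Fisher diffusion under the symmetric
  underdominant form of stabilizing selection, folded on MAF; it is the
  unique density satisfying `v(a,x) = 2a²x(1-x)·ℓ(a,x)` and is validated
  against the simulated equilibrium folded site-frequency spectrum.
- `v(a,x) = 4a²·exp(-a²x(1-x))` and `v(a) = 4a·D₊(a/2)` with `D₊` the Dawson
  function: `v ≈ 2a²` for `a² << 1`, peaks at `a² ≈ 10` (`v ≈ 5.13`), and
  tends to 4 as `a → ∞`.
- `f(a) = 2a³·exp(-a²/4)/(√π·erf(a/2))`. The defining property is
  `∂π/∂x(a,x) = 2f(a)/v(a,x)` where
  `π(a,x) = ∫₀ˣ e^{a²y(1-y)}dy / ∫₀¹ e^{a²y(1-y)}dy` is the diffusion
  fixation probability under stationary stabilizing selection and drift.
  The normalization uses `√π` — the unique choice consistent with that
  identity, which the test suite checks against numerical differentiation of
  `π` (a rendering of the formula with a bare `π` fails the identity by a
  factor `π^{-1/2}`).

`π` is evaluated through a closed form,
`π = [erf(a(x-1/2)) + erf(a/2)]/(2·erf(a/2))`, computed on the folded lower
half and reflected so that `π(a,x) + π(a,1-x) = 1` holds exactly, switching
to an erfc formulation when the erf arguments exceed 1 (a difference of
tails, immune to the cancellation that otherwise zeroes out probabilities
for `a ≳ 10`).

Expectations over `g` use adaptive quadrature on `S ∈ (0, 60·E(S)]` at
relative tolerance 1e-10; the integrands (`v`, `f`) are bounded, so the
dropped exponential tail carries weight < 1e-26. Non-convergence raises with
the quadrature diagnostics.

Initial MAFs for single-allele runs are importance-sampled: the proposal is
`∝ v(a,x)` (inverse-CDF on an 8193-point grid), with weights
`∝ ℓ/v ∝ 1/(x(1-x))` normalized to mean one. The proposal concentrates
replicas where variance — hence phenotypic response — resides, while the
weights recover expectations under the site density `ℓ`.

## Phenotypic and allelic response

The mean distance to the new optimum follows the moment recursion
`E(ΔD) = -(V_A/V_S)·D + (1-D²/V_S)·μ₃/(2V_S)`, iterated as a
discrete-generation difference equation (the simulators are discrete-time
and `t₁ >> 1` makes the continuous/discrete distinction negligible). With
constant moments its exact solution is geometric; the closed-form
`D_L(t) = Λ·exp(-V_A(0)t/V_S)` is kept as the continuous-time Lande curve.
Skewness is reported as `μ₃/V_A^{3/2}`; raw `μ₃` is also emitted.

Rapid phase (up to `t₁ = (V_S/V_A(0))·ln(Λ/δ)`): per-pair frequency gap
`(Λ-D_L(t₁))·2a·x₀(1-x₀)/V_A(0)`; contribution per unit input
`(Λ-D_L(t₁))·v(a,x₀)/V_A(0)` pointwise, `·v(a)` marginally. Long term, the
directional pulse plus the fixation-probability gradient give
`Λ·f(a)/V_A(0)` (linear Lande case, independent of initial frequency), and
`(1+C)·Λ·f(a)/V_A(0)` in the non-Lande case, split `(1+A)` standing / `B`
new mutations with `A+B = C = E_g[v]/E_g[f] - 1`. Only these *linear*
approximations are implemented; when `a(1+A)Λ/V_A(0) ≳ 1` the module warns
rather than silently extrapolating. `B` has no closed form here: it is
obtained as `C - A`, with `A` estimated from a mean-distance trajectory via
`A = [∫D dt]·V_A(0)/(V_S·Λ) - 1` (trapezoid plus an exponential tail
correction fitted to the trailing 10% of the series).

For fixation-excess tables, the instantaneous pulse is applied symmetrically
around a pair's initial MAF (`x₀ ± Δx/2`, the opposed allele clamped at 0),
and averages over `x₀` use quadrature against `ℓ(a,x)` truncated at
`1/(2N)`, matching the simulators' support. The relative increase in total
fixations is reported against the per-pair equilibrium baseline
`(π₊+π₋)/(2π_eq) - 1`, which is identical under per-site counting because
both alleles of a pair fix with probability `π_eq` at equilibrium.

## Simulation engines

All engines update selection → drift → mutation within a generation, so a
new mutation first experiences selection in the generation after it arises.
New mutations enter at count 1; absorption is exact attainment of count 0 or
`2N` after binomial sampling, after which the allele folds into the "fixed
background" (the fixed distance from the optimum is `optimum - background`).

- **All-alleles** (workhorse): per site, the expected frequency change under
  the *realized* population distance `D(t)` (not its expectation), then an
  independent `Binomial(2N, x')` draw per site — independence across sites
  is the linkage-equilibrium assumption, flagged as such. The stabilizing
  term keeps its `(1-D²/V_S)` factor at all times (it matters only
  immediately after the shift). Frequencies are clamped to [0,1] before
  sampling and clamping events are counted. Under linkage equilibrium the
  phenotypic moments are genic sums: `V_A = Σ2a²x(1-x)`,
  `μ₃ = Σ2a³x(1-x)(1-2x)`.
- **Individual-based**: genotype matrix per segregating site; parents drawn
  `∝ W(z)` through log-fitness (no underflow for extreme phenotypes),
  independent assortment per site, Poisson(`2NU`) mutations per offspring
  generation. Used to validate the linkage-equilibrium shortcut at small N.
- **Single-allele**: one focal allele per replica with `D(t)` imposed
  externally (analytic Lande curve, a simulated mean trajectory, or `D ≡ 0`
  for the stationary process); replicas vectorized with an active-set loop,
  capped at 100N generations (non-absorbed replicas are counted and warned
  about).

Replication: per-replicate RNG streams derive from the master seed by a
counter-based `SeedSequence(master, spawn_key=(r,))`, so any replicate is
reproducible in isolation and a rerun with the same master seed is
byte-identical. Aggregation reports mean ± SE (sample SD/√n; bands at
1.96·SE). Replicate failures are tolerated up to 20% and recorded in the run
manifest. The burn-in is 10N generations from an empty population and the
default post-shift horizon is 12N.

## Numerical and measurement choices

- `equilibrium_variance` returns δ² units; presets set
  `Λ = (multiple)·sqrt(V_A(0))` using the analytic equilibrium variance so
  that every replicate sees the same shift, while deviation summaries
  compare against `D_L` computed with the *measured* equilibrium variance
  (mean `V_A` over the final 2000 burn-in generations, pooled across
  replicates).
- Trajectory extrema (peak variance, maximum deviation from `D_L`, maximum
  |skewness|) are taken on the raw replicate-mean series: at the packaged
  replicate counts their standard errors are an order of magnitude below the
  measured signals, while any boxcar wide enough to suppress the residual
  drift noise would flatten the steep rapid-phase transient it is supposed
  to measure.
- The fixed-distance decay rate is a linear regression of
  `log(fixed distance)` on `t` over `t ∈ [0.5N, 6N]`, after reducing the
  series to 40 time-bin means and dropping bins within 3 SE of the
  asymptote. The asymptote defaults to 0 — its equilibrium expectation —
  rather than a tail estimate, which would be biased when the series has not
  fully converged (a tail estimate remains available as an option).
- The exponential-in-S family evaluates bin probabilities and quantiles in
  closed form; tabulated distributions must supply weights summing to 1
  within 1e-8.

## Scaled-down validation conditions

The full-resolution study conditions (N = 10⁴, 2500 all-alleles and 250,000
single-allele replicates, 12N horizons) are not desk-scale. The packaged
validation experiments shrink N while keeping the quantities the response
actually depends on:

- phenotypic response (non-Lande): N = 5000 with the *population-scaled*
  mutational input held at its study value, `2NU = 200` (so U = 0.02),
  squared effects Exponential(16), 20 replicates, burn-in 10N, horizon 2N,
  shift 4 SD;
- fixed-distance decay (Lande): N = 2000, U = 0.03, 10 replicates,
  horizon 8N;
- fixation-probability grid: N = 1000, 20,000 replicas per (S, x₀) point.

Holding `2NU` fixed is what makes the scale-down faithful: in δ units the
moment responses depend on the shift through `Λ/V_A(0)` and on the
architecture through `2NU` and `g` alone. The variance response in
particular is second order in the allelic pulse — proportional to
`Λ²/V_A(0)² ∝ 1/(2NU)` for a shift of fixed size in SD units — so reducing
`2NU` instead would double the measured peak. This was verified directly:
the all-alleles engine at N = 10⁴, U = 0.01 (analytic-equilibrium start plus
relaxation) gives a peak variance increase of ~12% and a maximum deviation
from `D_L` of ~0.07·sqrt(V_A(0)), and the N = 5000, U = 0.02 experiment
reproduces those values, while N = 5000 with U = 0.01 (2NU = 100) gives
~20% and larger skewness, exactly as the scaling law predicts.

One caveat of the reduced N: the shift `Λ = 4·sqrt(V_A(0)) ≈ 116 δ`
slightly exceeds `sqrt(V_S) = 100 δ` at N = 5000 (it is 0.82·sqrt(V_S) at
N = 10⁴), so the shift assumption is borderline there; the `(1 - D²/V_S)`
factor in the frequency dynamics handles it and the measured responses match
the full-scale runs.

Note that maximum skewness under these study conditions is ~0.05, not
arbitrarily small: during the quasi-static phase the plateau distance obeys
`D ≈ μ₃/(2V_A)`, so a visible plateau *requires* skewness
`2D/sqrt(V_A)` of that order. The simulated skew, plateau distance and
variance are mutually consistent with this identity throughout. The analytic
quantities are exact-scale and carry no such caveat.

## What the generator does and does not emulate

The synthetic populations realize exactly the model above: no linkage
disequilibrium (beyond what the individual-based engine generates at small
N), no pleiotropy, no dominance or epistasis, constant population size, a
single instantaneous optimum shift, and sign-symmetric effect distributions.
Passing tests therefore validate the theory *within this model class*; they
say nothing about confounds real data would add (LD between large-effect
alleles, pleiotropic costs, demography), which the analytic framework does
not cover.

## Known limitations

- Long-term contributions use the linear approximations only; for
  `a(1+A)Λ/V_A(0) ≳ 1` (very large effects or shifts) they are known to be
  inaccurate and the code warns.
- `ℓ(a,x)` omits O(1/N) boundary corrections near `x = 1/(2N)`; the
  SFS comparison against the all-alleles engine quantifies the residual
  rather than modeling it.
- The all-alleles engine uses independent per-site binomial drift rather
  than joint multinomial sampling; at `2NU >> 1` with free recombination the
  difference is negligible, but it is an assumption, not a theorem.
- Unfolded (polarized) spectra are out of scope: the model is symmetric and
  everything is folded on MAF.
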