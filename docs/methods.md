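# Methods

## Model

The individual life cycle is a finite-state, discrete-time absorbing
Markov chain. The τ transient states are the living stages (age classes or
size/stage classes); the α ≥ 1 absorbing states represent death. The
transient matrix **U** (τ×τ, columns = departure stage) must have spectral
radius strictly below 1 (checked via the dominant eigenvalue magnitude with
tolerance 1e−10), so absorption is certain. The full column-stochastic
chain is **P** = [[**U**, 0], [**M**, **I**_α]]; with a single absorbing
state the mortality row is the column deficit **M** = **1**ᵀ − **1**ᵀ**U**,
with several it must be supplied. The fundamental matrix
**N** = (**I** − **U**)⁻¹ is computed by LU solves against identity
columns, never by forming an explicit inverse inside the pipelines; its
column sums are the life expectancies.

Each transition j → i carries a random reproductive reward whose k-th raw
moments are collected in the s×s matrices **R**ₖ (s = τ + α). In the
common stage-specific case, **R**₁ = **1**ₛ(**f**ᵀ | **0**): every row
equals the padded mean-fertility vector, so the reward is also collected
on the step into death. If reproduction requires parental survival, the
absorbing-destination rows are zeroed instead; this is an explicit flag,
off by default, and all higher-moment constructors preserve the zeroed
rows. Higher moments come from one of four models:

- *Bernoulli* (single offspring; mean = probability): **R**₃ = **R**₂ = **R**₁;
- *Poisson* (clutches with equal chances): **R**₂ = **R**₁ + **R**₁∘**R**₁,
  **R**₃ = **R**₁ + 3**R**₁∘**R**₁ + **R**₁∘**R**₁∘**R**₁;
- *fixed* (degenerate at the mean): **R**ₖ = **R**₁ raised entrywise to k;
- *empirical*: raw moments per stage supplied directly, with the Jensen
  consistency f₂ ≥ f₁² enforced.

## Moments and statistics of LRO

Writing **Z** = (**I**_τ | **0**) and **R̃**ₖ = **ZR**ₖ**Z**ᵀ, the raw
moments of remaining LRO by starting stage satisfy the closed recursion

ρ̃ₘ = **N**ᵀ**Z**(**P**∘**R**ₘ)ᵀ**1**ₛ + Σₖ₌₁^{m−1} C(m,k) **N**ᵀ(**U**∘**R̃**ₘ₋ₖ)ᵀρ̃ₖ.

The cross terms use the transient submatrices **R̃**: the reward of the
dying step enters only through the direct term, since no future output
follows it. Each order costs one linear solve against (**I** − **U**)ᵀ.
From the first two or three moments follow the variance
V = ρ̃₂ − ρ̃₁∘ρ̃₁, SD, CV, Crow's index 𝓘 = CV², and the standardized
third central moment (skewness). CV, 𝓘, and skewness are reported as NaN
where the mean (resp. SD) is zero rather than raising. Statistics are
reported for every starting stage; the headline row is stage 1 (birth).
Variance values within −1e−9 (relative) of zero are clipped to zero as
roundoff; anything more negative raises.

The variance splits by the law of total variance into V_between
(divergence of pathways through the life cycle) and V_within (stochastic
fertility along pathways). V_between is obtained by recomputing the
variance under the fixed reward model with the same means — which removes
all within-pathway noise — and V_within by subtraction, so the partition
identity holds to machine precision by construction; materially negative
within-components raise a moment-inconsistency error.

## Sensitivity analysis

For a parameter vector θ (length p), the derivative of each moment vector
is assembled from three blocks:

- **V**ᵢ differentiates the current-step reward term through
  d(**P**∘**R**ᵢ) — elementwise products of **R**ᵢ with d vec **P** and of
  **P** with d vec **R**ᵢ, followed by column sums restricted to the
  transient rows;
- **W**ᵢ,ⱼ differentiates the cross terms, including the recursive
  dependence on lower-order dρ̃ᵢ;
- **X**ᵢ carries the derivative of the fundamental matrix itself, via
  d**N** = **N**(d**U**)**N**, which reduces to d**U**ᵀρ̃ᵢ inside the
  common **N**ᵀ[·] factor.

Then dρ̃ₘ/dθᵀ = **N**ᵀ[**V**ₘ + Σₖ C(m,k)**W**ₖ,ₘ₋ₖ + **X**ₘ], built
bottom-up in m. Although these blocks are conventionally written with
vec-permutation matrices and Kronecker products, all identity- and
one-vector-factored Kronecker products are applied implicitly by reshaping
(s², p) stacks into (s, s, p) arrays, so no s²×s² operator is ever
materialized; the dense vec-permutation matrix is still exposed
(`vec_permutation`) and the dense block formula for d vec **P** is used as
a cross-check in the tests. With α = 1, d vec **P** follows from
d vec **U** (the death row absorbs the column deficits); with α > 1 the
caller must supply d vec **P** (or equivalently d vec **M**), since no
general construction exists.

Statistic derivatives follow by the chain rule: dV = dρ̃₂ − 2𝒟(ρ̃₁)dρ̃₁,
dSD = ½𝒟(SD)⁻¹dV, dCV = 𝒟(ρ̃₁)⁻¹dSD − 𝒟(SD)𝒟(ρ̃₁)⁻²dρ̃₁, and
d𝓘 = 2𝒟(CV)dCV. Rows where SD = 0 or the mean is 0 are NaN. Elasticities
are 𝒟(ξ)⁻¹(dξ/dθᵀ)𝒟(θ), defined only for ξ > 0 and θ ≥ 0; columns with
θⱼ = 0 are set to 0, the limiting value.

Ready-made perturbation maps:

- **Age-classified mortality** (θ = μ): **U** has survival exp(−μₓ) on the
  subdiagonal (optionally a final self-loop for an open-ended last
  interval), so dU₍ₓ₊₁,ₓ₎/dμₓ = −exp(−μₓ) on the structural pattern and
  d**R**ₖ = 0.
- **Age-classified fertility** (θ = f, Bernoulli): all moment matrices
  equal **R**₁, so every order shares d vec **R**ₖ/dfᵀ = (**Z**ᵀ ⊗ **1**ₛ).
- **Stage survival/mortality** through **U** = **GΣ** (Σ = 𝒟(σ),
  σ = exp(−μ), **G** column-stochastic conditional transitions):
  dU₍ᵢ,ⱼ₎/dσⱼ = G₍ᵢ,ⱼ₎, and the μ map scales columns by −σⱼ. When no
  survival vector is given, σ defaults to the column sums of **U** —
  documented because the factorization is otherwise non-unique; this
  choice attributes all column deficit to mortality and makes **G**
  column-stochastic by construction.
- **Compensated growth** (θ = vec **G**): perturbing g₍ₗ,ᵢ₎ redistributes
  −g₍ₖ,ᵢ₎/(1 − g₍ₗ,ᵢ₎) over the other entries of column i, preserving the
  column sum and the proportional structure of the remainder. If a
  perturbed entry equals 1, its column holds no other mass and no
  proportional reallocation exists; by default that direction is applied
  uncompensated (the compensation block is zero there, the natural limit
  of "redistribute over nothing"), and `strict=True` raises instead. The
  default keeps pure-stasis columns — common in real matrices, e.g. the
  largest size class of the bundled hemlock model — analyzable.
- **Fertility moments**: mean with variance held fixed
  (df₂/df₁ᵀ = 2𝒟(f₁)), variance with mean held fixed (d**R**₁ = 0,
  d**R**₂ = (**Z**ᵀ ⊗ **1**ₛ); rejected for Bernoulli, whose mean pins the
  variance), and the linked mode where higher moments slide along the
  Poisson or Bernoulli family.

Every map, and the full chain from parameters to Crow's index, is
validated against central finite differences (step 1e−6·max(1, |θⱼ|),
relative tolerance 1e−5 with an absolute floor of 1e−8 — the package's own
bar). The finite-difference oracle re-derives all downstream matrices from
the perturbed parameters, including the *nonlinear* proportional
compensation path for **G**, so it exercises the machinery end to end and
never touches the analytic derivative code.

## Simulation oracle

The individual-based sampler draws trajectories from the columns of **P**
(inverse-CDF per departure stage) and a reward per step from the stage's
fertility distribution (Bernoulli, Poisson, fixed, or a two-point
empirical distribution on {0, f₂/f₁} matching the first two moments),
including the dying step unless parental survival is required. Besides
LRO and lifespan it records each path's conditional mean and variance of
LRO — visit counts times stage moments, exact given the path — whose
sample variance and sample mean estimate V_between and V_within without
nested simulation. The generator is NumPy's PCG64; a seed is mandatory in
the CLI and results are bit-reproducible given one. Stage groups are
processed in sorted order each step, which fixes the stream order.

## Synthetic life-cycle generator

`generate_synthetic_model` draws random valid life cycles used throughout
the validation suite. The `stage_like` profile draws each column of **G**
from a Dirichlet(1.5) and shrinks it toward uniform (0.85·g + 0.15/τ), so
no conditional transition approaches 0 or 1 and the compensated-growth
map is well-conditioned; survivals are uniform on (0.2, 0.99), so the
spectral radius of **U** = **GΣ** is below 1 by construction. Fertility
means are strictly positive in every stage — uniform (0.1, 2.0) offspring
per step for Poisson/fixed/empirical, (0.05, 0.95) for Bernoulli — so CV
and 𝓘 are defined from every starting stage. The `age_like` profile draws
hazards uniform on (0.02, 0.4) per age and a unimodal Gaussian-shaped
fertility window (peak 0.3–0.9, floor 0.02) with Bernoulli rewards,
emulating a generic iteroparous age-classified schedule. These are
plausible vital-rate ranges, not fits to any population: models drawn this
way have modest lifetimes and fertilities, so passing tests demonstrate
correctness of the machinery, not coverage of extreme life histories
(near-singular **I** − **U**, vanishing means, or heavy-tailed empirical
fertilities), and say nothing about heterogeneity between individuals,
which the framework deliberately excludes.

## Problem sizes and numerical choices

The validation battery uses 50 random models with τ ≤ 5 for the
finite-difference suite (all six perturbation maps each) and 10⁵
trajectories per model for the Monte-Carlo comparisons, with agreement
required within three Monte-Carlo standard errors — sizes at which the
whole suite and the acceptance script complete in seconds while the
3-SE bands are already tight. Matrices are read/written as headerless CSV
at %.17g so file round-trips are bit-exact; probability validations use
1e−9 tolerances; column-stochasticity of constructed chains holds to
1e−12. User-facing stage labels are 1-based (stage 1 … τ); arrays are
0-based internally.

## Known limitations

- Moments are computed up to order 3 by the schedule builders (the
  recursion itself is general in m; pass larger reward collections for
  higher orders).
- The full distribution of LRO has no closed form here; use the
  simulation oracle for distributional questions.
- Sensitivities of the variance-partition components, second-order
  sensitivities, and time-varying (periodic/stochastic) environments are
  out of scope.
- The bundled hemlock matrix is transcribed at its published precision;
  entries carry as little as one significant digit (the stage-1→2 growth
  probability 0.004), and stage-1 statistics — mean LRO in particular,
  which is nearly proportional to that entry — inherit that rounding
  uncertainty. Analyses of an unrounded database export will differ
  accordingly.
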