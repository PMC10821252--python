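# Methods

## Model

One-sample Mendelian randomization with individual-level data. For each
individual: `J` instruments **Z** (standardized minor-allele counts), a
standardized continuous exposure `X`, a binary outcome `Y`, and a scalar
latent confounder `U`:

- `U ~ N(0, 0.1)` (mean/variance convention throughout),
- `X | Z, U ~ N(Σ αₖ Zₖ + δₓ U, σₓ²)`,
- `Y | X, U ~ Bernoulli(expit(ω + β X + δ_y U))`.

The instruments are assumed valid (no pleiotropy: `Y ⫫ Z | X, U`;
confounder independence: `Z ⫫ U`). `δₓ` and `δ_y` are identified only
through their product, so tests and summaries report `δₓ·δ_y`
(`PosteriorDraws.delta_product`), never the factors.

Priors: `αₖ ~ N(0.5, 0.2²)` iid; `σₓ ~ Inv-Gamma(3, 2)` (shape/scale, on
the SD); `β` under the *used* prior `N(0, 10²)`; `ω, δₓ, δ_y ~ N(0, 1)`
(weakly informative — the model statement leaves these open, and unit
scale is generous for log-odds coefficients and standardized-exposure
regression). `U` enters both the exposure and outcome equations with
one shared per-individual value, matching the single-confounder graph.

Missing exposures are unknowns of the model, given the same conditional
distribution as observed ones; imputation and inference are simultaneous.

### Interval null and mixture prior

The causal null is the ROPE `H₀: |β| ≤ T`. The intended ("true") prior
for β is the mixture `π₀·Unif(−T, T) + (1−π₀)·N(0, 10²)`. Sampling runs
under the continuous component alone; every retained draw gets weight
`ω(β) = p_true(β)/p_used(β)`, which is exactly `1 − π₀` outside the
ROPE and `(1 − π₀) + π₀/(2T·N(β|0,10²))` inside. Two estimators of the
ROPE posterior mass `V₀` are provided: the normalized weight mass inside
`[−T, T]` (default — same expectation, no resampling noise) and the
inside-proportion of an explicit weighted resample (used when draw-level
true-posterior inference on the other unknowns is wanted). The ternary
rule: odds `V₀/V₁ > 10` accept the null, `< 0.1` claim a discovery,
the closed band `[0.1, 10]` is an uncertain outcome; `V₁ = 0` maps to
`+inf` (accept null) and `V₀ = 0` to `0` (discovery), with no
pseudo-count smoothing — the raw small-`V₀` instability is a documented
property of the estimator, and enough retained draws (K ≳ 2000) are the
remedy.

### ROPE elicitation

`risk_shift(p, β) = expit(logit(p) + β)` translates a candidate effect
magnitude into an absolute risk change at baseline risk `p` (with a
logistic outcome model and standardized exposure, β is a per-SD log-odds
shift). A practitioner picks T as the largest β whose implied risk
shifts they would call negligible.

## Sampler

The posterior over all unknowns (parameters, latent `U`, missing `X`) is
sampled by Metropolis-within-Gibbs, exploiting structure:

- `α` (J-dimensional) and `δₓ`: exact conjugate Gaussian full
  conditionals from the linear exposure equation;
- `σₓ`: random-walk Metropolis on `log σₓ` (the Inv-Gamma prior sits on
  the SD, so no standard conjugate update applies);
- `ω, β, δ_y`: scalar adaptive random-walk Metropolis;
- `U` and missing `X`: conditionally independent across individuals
  given the globals, updated by vectorized per-individual moves —
  random-walk for `U`, and for missing `X` an independence proposal from
  its Gaussian full-conditional prior accepted on the Bernoulli term.

Scalar proposal scales adapt during warmup only (Robbins–Monro toward
44% acceptance) and are frozen afterwards, so retained draws target the
exact posterior. Chains start from mildly overdispersed draws so that
split-R̂ can detect non-convergence. Defaults: 4 chains × 2000
iterations with half discarded as warmup (desk scale; any larger budget
is a constructor argument away). Determinism: one root seed, per-chain
and per-replicate substreams spawned via `numpy.random.SeedSequence`.

Diagnostics are the classic split-R̂ and a Geyer-truncated
autocorrelation ESS on the β chain; constant chains yield NaN (flagged,
not fatal), a single chain is an error. At the default budget on the
simulation scenarios below, β chains typically show R̂ < 1.02 and
ESS in the hundreds; the tests cross-check the implementation against
arviz on synthetic chains.

## Synthetic data and the simulation experiment

`simulate_pool` generates a pool of 1000 individuals: independent
biallelic SNPs in Hardy–Weinberg proportions with per-SNP MAF ~
Uniform(0.1, 0.5) (drawn once per dataset), standardized at pool level;
then `U`, `X`, `Y` from the model with all `αₖ` equal. `split_and_mask`
draws the analysis sample of 400 without replacement and masks the
exposures of the last `n_B = n − round(n·(1−missing rate))` selected
individuals (round half away from zero; the 80% rate gives
`n_A = 80, n_B = 320`). Pre-masking values are retained in a hidden
oracle field for test bookkeeping only.

The factorial experiment crosses missingness (80%, 40%, 0%), instrument
strength (α = 0.3, 0.1, 0.05) and effect size (β = 0.3, 0): 18
scenarios; at the full 200 replicates, 3600 datasets. Throughout,
`δₓ = δ_y = 1`, `J = 15`, generation intercept `ω = 0`. The exposure
residual SD is fixed at `σₓ = 1` — the mean of its Inv-Gamma(3, 2)
prior and the companion of the fixed unit confounding coefficients.
Drawing `σₓ` from its prior per dataset is available
(`sigma_x_true=None`) but is not the default: it makes a sizeable
fraction of datasets intrinsically uninformative regardless of the
nominal instrument strength, which defeats the purpose of an
instrument-strength factor (we verified the resulting decisions against
an independent two-stage frequentist fit; the weak datasets are real,
not a sampler artifact).

Per simulated dataset the analysis pipeline standardizes `(Z, X)` —
the model's stated scale; note this means the standardized-scale true
effect is `β·sd(X) ≈ 0.47` when `β = 0.3` under the design above —
fits the used posterior, reweights, and applies the ternary rule with
`(T, a)` drawn afresh per dataset from `T ~ Unif(0.01, 0.1)`,
`a ~ Unif(0, 0.6)`. The IVW comparator regresses `X` on each `Zⱼ` in
the complete-data part A (OLS) and `Y` on each `Zⱼ` in the masked part
B (logistic), pools the ratio estimates with first-order fixed-effect
weights `wⱼ = γ̂ⱼ²/se(Γ̂ⱼ)²` (numerically free of small-`γ̂`
blow-ups), and accepts the null iff the 95% CI covers 0 (closed
interval). With 0% missingness there is no natural part B, so the
sample is split at random into halves for the two association stages —
a construction of this package, needed because a two-sample method has
no canonical one-sample form.

Losses follow the six-entry table (0 correct-confident, 1
wrong-confident, `a` uncertain); expected loss is the empirical mean
over replicates sharing a truth condition, equivalently the four-term
frequency-weighted formula. For the binary IVW rule the two uncertain
terms are structurally zero, and its loss surface over `(T, a)` is flat
by construction — the rule never consults either parameter.

## What the generator does not emulate

Linkage disequilibrium among instruments, pleiotropic (invalid)
instruments, sample overlap between the two IVW stages, covariate
adjustment, and case-control ascertainment are all absent. Passing
tests therefore demonstrate correctness of the machinery and the
method's operating characteristics under valid-instrument assumptions,
not robustness to their violation.

## Numerical choices and degenerate inputs

- Standardization uses observed-data sample moments (ddof = 1); a
  monomorphic genotype column is an explicit error naming the column.
- `log_joint` is finite for all finite parameters with `σₓ > 0`;
  Bernoulli terms use the `logaddexp` form.
- All importance weights are ≥ `1 − π₀`, so the resampling step cannot
  degenerate unless `π₀ = 1` with no draw inside the ROPE (explicit
  error).
- Odds thresholds are inclusive into the uncertain band; CI endpoints
  exactly at 0 count as covering 0.
- Replicate failures inside the experiment driver are logged and
  collected, never silently dropped.

## Scale of the shipped checks

The test suite runs the experiment at desk scale — single scenarios,
20 replicates, 2 chains × 1500–2500 iterations — chosen so the entire
suite completes in about a minute while leaving clear margins on the
behavioral assertions (e.g. measured strong-instrument discovery rate
0.85 against a 0.80 bound, Bayesian expected loss 0.036 in the strong
scenario). Paper-scale runs (200 replicates, longer chains, full grid)
use the same entry points with different arguments.
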