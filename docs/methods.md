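# Methods

## Estimand and identification

For a binary exposure A and an orderable outcome Y with potential outcomes
Y(1), Y(0), the target is the Mann–Whitney-type causal effect
θ = E[h(Y_i(1), Y_j(0))] for independent units i ≠ j, with the
tie-splitting kernel h(y₁, y₀) = I(y₁ > y₀) + ½·I(y₁ = y₀). θ depends only
on the two marginal potential-outcome distributions. Under the four
standard assumptions — consistency, no interference, ignorability of A
given covariates X, and positivity — each marginal CDF is identified by
standardization: F_{Y(a)}(y) = E_X[P(Y ≤ y | X, A = a)]. The covariate
distribution is estimated by its empirical counterpart (all n rows, both
arms); the conditional CDF by the model below.

## The cumulative probability model and its NPMLE

The conditional model is G[P(Y ≤ y | X, A)] = α(y) − βᵀX − τA: a linear
transformation model whose monotone transformation is absorbed into the
intercept function α, estimated as an increasing step function with one
step per unique outcome value. With J unique values the nonparametric
likelihood is the multinomial likelihood of a cumulative link model with
J − 1 free intercepts (α₀ = −∞, α_J = +∞ at the boundary); J = n for fully
continuous data. The NPMLE maximizes it jointly over (α, β, τ). Fitted
slopes, cell probabilities, and everything downstream are invariant to
strictly increasing transformations of Y.

Numerical scheme:

- **Monotone parameterization.** The optimizer works on
  (α₁, log(α₂−α₁), …), so every iterate is a valid increasing intercept
  vector and line searches never leave the feasible region.
- **Optimizer.** L-BFGS-B with the analytic gradient (the α-gradient is
  accumulated by bincount over outcome ranks, then chained through the
  log-difference coordinates). Defaults: relative log-likelihood tolerance
  1e-11, projected-gradient max-norm 1e-6, 1000 iterations. The closed-form
  null solution — α from the link-transformed empirical CDF, clipped to
  [1/(n+1), n/(n+1)], with β = τ = 0 — is the starting point, so the null
  model converges in zero iterations and fitted models start in a good
  basin. Fits at n = 500 (≈500 parameters) take ~20–50 ms.
- **Probability floor.** Cell probabilities are clipped at 1e-12 inside the
  log. A solution still touching the floor is flagged non-converged: it
  signals boundary escape (e.g. a treatment arm occupying an extreme
  outcome block, where τ̂ diverges), not a genuine NPMLE.
- **Failure is data.** `fit_cpm` never raises on non-convergence; it
  returns the flag plus diagnostics (iterations, gradient norm, optimizer
  message). Batch callers — the bootstrap and the simulation engine — drop
  and count failed fits, mirroring how convergence-failure percentages are
  reported in applied work with these models.

Links: probit (standard-normal errors), logit (logistic), and log-log,
defined here as G(p) = −log(−log p) applied to P(Y ≤ y) (extreme-value
errors). Some ordinal-regression software parameterizes exceedance
probabilities P(Y ≥ y) instead; coefficient signs then flip, but θ̂ is
unaffected when one convention is used consistently. Link round-trip
accuracy is limited by double precision near the upper tail (1 − F(x)
under-resolves beyond x ≈ 4 for probit), which bounds the testable
round-trip range per link but has no effect on fitting, where only F and
its density are evaluated.

## From fitted model to θ̂

The marginal CDFs are evaluated on the grid of unique outcome values with
the boundary conventions F̂(y₍₀₎) = 0 and F̂(y₍J₎) = 1, and θ̂ is the double
sum Σ_{k,l} h(y₍ₖ₎, y₍ₗ₎) pmf₁[k] pmf₀[l], computed by the equivalent O(J)
accumulation Σ_k pmf₁[k]·(cdf₀[k−1] + ½·pmf₀[k]). All (i, j) pairs are
included, i = j among them; a variant excluding same-observation pairs
(renormalized over off-diagonal mass) is available via
`estimate_theta(..., exclude_diagonal=True)`. The inclusive tie-split
default pulls θ̂ toward ½ by roughly (θ − ½)·Σ pmf₁pmf₀ ≈ O(1/n) — visible
only at small n and part of the estimator's definition here.

Exact properties, enforced by the test suite: θ̂ ∈ [0, 1]; θ̂ = ½ when the
two marginal CDFs coincide; relabeling A → 1−A maps θ̂ → 1−θ̂ (to optimizer
precision); θ̂ is unchanged by strictly increasing transformations of Y.

## Bootstrap inference

Nonparametric row resampling (size n, with replacement; optional
stratification by arm). Default interval: θ̂ ± 1.96·SD of the B bootstrap
estimates, clipped to [0, 1]; percentile interval available. Resamples
whose refit fails are dropped and counted; more than 10% failures raises,
since the SD would then be unreliable. Resampled datasets are re-indexed on
their own unique-value grids.

## Parametric comparison estimator

OLS of g(Y) on (1, X, A) for g ∈ {identity, log, sqrt}, residual SD with
denominator n − p − 2. Since g is strictly increasing, comparisons transfer
to the transformed scale, where potential outcomes are Gaussian under the
model; standardizing both arms over the empirical covariate rows gives the
exact pairwise form θ̂ = (1/n²) Σ_{i,j} Φ((τ̂ + β̂ᵀ(x_i − x_j))/(σ̂√2)) —
the continuous-outcome limit of the discrete plug-in double sum (verified
against numeric integration in the tests). It is exactly ½ when τ̂ = 0 and
satisfies the same relabel symmetry as the CPM path.

## Simulation engine

The generator draws X ~ N(0,1), A from logit P(A=1|X) = γ₀ + γ₁X with
γ = (−0.5, 0.75), and Y = exp(βX + τA + ε), ε ~ N(0,1) — a confounded,
heavily right-skewed design in which the probit CPM with linear predictor
βX + τA is exactly correct while any fixed-transform normal model is
correct only for g = log. The error SD is 1; this resolution is pinned by
the true-θ oracle below. β controls confounding strength, τ the treatment
effect; defaults β = τ = 0.5 are mid-grid values of the design.

True θ has the closed form Φ(τ/√(2β² + 2)) because
log Y_i(1) − log Y_j(0) is Gaussian for independent units. The closed form
is only trusted because a pairwise Monte Carlo oracle (independent draws of
(X, ε) pairs; 10⁷ pairs give SE ≈ 1.6e-4) reproduces it to < 0.001 at all
nine (β, τ) grid points — the property suite re-checks this.

`run_scenario` spawns one child seed per replicate from the scenario seed
(results identical under any parallelism), applies the requested estimator
— CPM with correct or confounder-omitting linear predictor and any link,
or a transformed normal linear model — and summarizes bias, SD, RMSE
(rmse² = bias² + variance holds by construction) and, when `boot_B ≥ 2`,
coverage of the 95% bootstrap-SD interval. Failed replicates are dropped
and counted; >20% failures flags the cell unreliable. Paired estimators
requested via `compare_estimator` run on the same simulated datasets
(common random numbers), which tightens SD/RMSE-ratio comparisons.

Default scales are desk-sized: 200 replicates per cell (300–400 in the
acceptance script) and 100 bootstrap refits for coverage runs, giving
Monte Carlo SEs of a few thousandths on bias and ~0.015 on coverage;
full-scale runs (1000 replicates, 200 refits) are a configuration choice
away and change no interfaces.

What the generator does **not** emulate: real biomarker data's detection
limits and heaping, multi-dimensional and mixed-type confounding,
treatment-effect heterogeneity, and any violation of ignorability. Passing
tests therefore certify the estimator's behavior under a correctly
specified (or deliberately singly-misspecified) rank-linear DGP, not
robustness to those features. The `mock_cohort` fixture is shaped like a
kidney-biomarker cohort (right-skewed outcome, ~75% exposed, mixed
covariates) but is entirely synthetic and used only for interface testing.

## Known limitations and open choices

- Standard errors for (β̂, τ̂) via the information matrix are out of scope;
  inference is bootstrap-only, matching the estimator's intended use.
- Whether coverage simulations should drop or retain replicates whose
  bootstrap contained failed refits is not standardized anywhere; here
  failed refits are dropped within a replicate (counted), and a replicate
  is dropped only if its primary fit fails.
- The small-sample (n ≈ 50) bias of θ̂ depends at order 1/n on the
  tie-handling convention of the plug-in double sum; this package's
  inclusive tie-split kernel is one defensible choice among near-equivalent
  variants that coincide as n grows.
- Separation-like configurations legitimately prevent NPMLE convergence;
  they surface as flagged failures, and a high failure rate is itself a
  useful diagnostic of link or predictor misspecification.
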