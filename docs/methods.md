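# Methods

## Model

Phenotypes follow the reaction-norm (Finlay–Wilkinson) model

```
y_ijk = μ + g_i + h_j + b_i·h_j + ε_ijk,   ε_ijk ~ iid N(0, σ²_ε)
```

with variety main effects `g_i`, environment main effects `h_j`, and
slope deviations `b_i` (expected response per unit environment effect is
`1 + b_i`). Replicates (index k) are allowed; variety and environment
identifiers are opaque labels ordered by first appearance in the input
table, so every output vector has a reproducible order independent of
locale or label content. The literal string `NA` (case-sensitive) and an
empty field both parse as a missing trait value; variety/environment
labels may never be missing.

## Two-step OLS estimator

Step one solves the additive model `y = μ + g_i + h_j + ε` by least
squares under the identification constraints Σ_i g_i = 0 and Σ_j h_j = 0,
via the bordered (Lagrange) normal equations with a dense symmetric
solver. The variety/environment incidence graph must be connected and
every environment must have at least one observed record, otherwise the
constrained system is singular and the offending component or environment
is named in the error. On a complete balanced design the solution reduces
exactly to `ĥ_j = environment mean − grand mean`, `ĝ_i = line mean −
grand mean`.

Step two regresses, separately within each line, the observed phenotypes
on `ĥ` with an intercept but no separate overall mean: the intercept
estimates `μ + g_i` and the slope `1 + b_i`. The reported residual
variance pools the within-line regressions weighted by their residual
degrees of freedom, `Σ_i RSS_i / Σ_i (n_i − 2)`. Replicate records enter
the regression individually (not as cell means). A line observed at fewer
than two distinct `ĥ` values cannot support a slope: it receives
`b̂_i = 0` and intercept = line mean − mean(ĥ at its records),
contributes no degrees of freedom, and is flagged in a per-line status
vector. Both steps treat effects as fixed and use only non-missing
records; `ŷ` is nevertheless produced for every record through the
predictor identity `ŷ = μ̂ + ĝ_i + (1 + b̂_i)ĥ_j`.

## Bayesian estimator

All effects are random: `g ~ N(0, A σ²_g)`, `b ~ N(0, A σ²_b)`,
`h ~ N(0, H σ²_h)`; μ has a flat prior; each variance has a
scaled-inverse-χ²(df, S²) prior with mean `df·S²/(df−2)` for df > 2. A
and H default to identity (independent effects). Inference is by Gibbs
sampling with block updates in the fixed scan order μ, g, b, h, σ²_ε,
σ²_g, σ²_b, σ²_h:

* given the rest, each coefficient block is multivariate normal with
  precision `diag(D)/σ²_ε + K⁻¹/σ²_u`, where D collects per-level sums of
  squared covariates (counts for g; `h_j²` for b; `(1+b_i)²` for h) and
  the location solves `P·m = r/σ²_ε` with r the covariate-weighted
  partial residuals. When K is the identity the precision is diagonal and
  the update is elementwise O(n_obs); otherwise the q×q system is solved
  through a fresh Cholesky factorization each cycle (q is at most a few
  hundred here, so exactness is cheaper than single-site schemes);
* each variance is scaled-inverse-χ² with df + q degrees of freedom and
  scale `(uᵀK⁻¹u + df·S²)/(df + q)` (residual version: RSS and n_obs).

Records with missing phenotypes contribute to no likelihood sum; they are
not imputed as latent variables. This keeps the chain identical whether
or not missing records are present, leaves prior-only environments
well defined (the mechanism behind predicting an unobserved environment
through H), and still yields `ŷ` and its posterior SD for every record
since the predictor is a deterministic function of the parameters. The
posterior SD of `ŷ` is computed from per-draw predictor values, not a
delta method.

Numerical details: A⁻¹ and H⁻¹ are computed once per run; if the
factorization fails (marker-derived kinships are often numerically
singular) a diagonal jitter of `1e-8·mean(diag)` is added once, with a
logged warning. Covariance inputs are validated at construction instead
(symmetry within 1e-8 relative, eigenvalues ≥ −1e-8 of the largest);
invalid matrices are rejected rather than silently repaired.
Initialization is cheap — μ at the observed mean, g = b = 0, h at
centered environment means (0 for data-free environments), variances at
their prior expectations — and relies on burn-in; with no observed data
at all the μ update is skipped (its flat-prior conditional is improper)
and the chain samples the prior. Non-finite draws abort with the cycle
number. `gibbs_cycle` accepts an `update=` subset so callers can clamp
blocks, which is how the test suite verifies each full conditional in
isolation against its closed form.

Chains: `n_chains` independent chains with child seeds derived
deterministically from (seed, chain index); identical inputs and seed
reproduce results bit for bit. Defaults are 5000 cycles, 3000 burn-in,
thinning 5, one chain; posterior means/SDs are computed from the thinned
post-burn-in draws (consistent with the persisted sample store), one
output column per chain. The thinned draws of the four variances, μ, and
the first two varieties' g/b and first two environments' h (overridable)
are kept and optionally persisted as one CSV per chain plus a JSON
config sidecar. No sign or centering constraint is imposed on h or b
inside the sampler; the zero-mean priors regularize location. Because μ
is flat, it absorbs the mean of h — only contrasts among environment
effects are strongly identified, which matters below.

### Default hyperparameters

Unless supplied, df = 5 for all four variances and scales are set so the
prior expectations partition the sample variance of the observed
phenotypes: `E[σ²_ε] = 0.5·Var(y)`, `E[σ²_g] = E[σ²_b] = 0.25·Var(y)`,
`E[σ²_h] = 0.5·Var(y)`, hence `S² = E·(df−2)/df`. The environment
variance deliberately gets a generous share because the number of
environments is usually tiny and its posterior accordingly wide and
skewed. df ≤ 2 is accepted (the prior then has no finite mean but the
posterior is proper) with a warning.

## Synthetic data

The generator produces tables with exactly the model's structure:
`g ~ N(0, Aσ²_g)`, `b ~ N(0, Aσ²_b)`, `h ~ N(0, Hσ²_h)` or fixed, iid
normal errors, full-factorial designs with optional replicates. Defaults
(300 lines × 8 environments, μ = 4, variances 0.3/0.09/0.10/0.9) mirror
the magnitudes of a several-hundred-line wheat yield trial in a handful
of environments. Kinships are VanRaden-style cross-products of centered,
scaled iid binomial dosages (allele frequencies uniform on the MAF
range); an optional full-sib family mode (offspring of simulated parent
pairs) produces genuinely structured relatedness (~0.5 within families),
since unrelated iid lines give a near-identity kinship under which a
kinship-aware prior cannot demonstrate its advantage. No linkage
disequilibrium or population structure beyond families is modelled, and
no non-normal errors or heterogeneous per-environment variances — so
passing tests show correctness of the estimators under the model's own
assumptions, not robustness to their violation in real trials. The
masking utility hides exactly one (randomly chosen) observed environment
per line, the standard partition for prediction-accuracy studies.

## Diagnostics

HPD intervals use the shortest contiguous window over sorted draws
covering ⌈mass·n⌉ points (ties to the lowest index). Monte Carlo
standard errors use batch means with ⌊√n⌋ batches. Autocorrelation is
the biased-normalization empirical estimate. Prediction scoring is plain
Pearson correlation over a supplied index set, with zero-variance inputs
reported as undefined (NaN). Multi-chain fits keep per-chain columns;
pooling across chains is left to the caller so as not to mask
non-convergence. Formal multi-chain diagnostics (e.g. potential scale
reduction) are out of scope — the persisted draws are plain CSV so any
MCMC toolkit can compute them.

## Design notes and known limitations

* The sampler's μ and h mix slowly in this multiplicative model; for
  final analyses run longer chains than the defaults and check the
  batch-means SEs (the examples use 10–50k cycles).
* With q environments small (the usual case), σ²_h is weakly identified:
  its posterior concentrates on the realized mean-centered spread of the
  q environment effects (about q−1 effective χ² degrees of freedom,
  since μ absorbs the mean of h). Fixed-truth simulation studies should
  therefore expect 95% HPD coverage of the *generative* σ²_h to fall
  well below nominal at, say, q = 8 — the parameter-recovery test
  observes exactly this, while coverage for σ²_ε, σ²_g, σ²_b (informed
  by hundreds of levels or records) meets the nominal target. This is an
  identification property, not a sampler defect; the conditional-law
  tests verify every full conditional exactly.
* The OLS path cannot estimate an environment with no observed records
  (it errors); the Bayesian path handles it, informatively so only with
  a non-diagonal H.
* Problem sizes in the tests and the acceptance script (hundreds of
  lines, thousands of Gibbs cycles, tens of cross-validation replicates)
  were chosen as the smallest sizes at which the statistical contrasts of
  interest are clearly resolved.
* Surplus labels in a covariance matrix are dropped after subsetting to
  the table's labels; a table label missing from a supplied matrix is a
  hard error naming the label.
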