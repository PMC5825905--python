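# Methods

This note documents the statistical machinery in `regplsc`: the model, the
estimators, the tuning and inference procedures, the synthetic populations
the simulation harness generates, and the numerical conventions. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

A recursive structural equation model with reflective measurement:

* Latent variables ξ (exogenous) and η (endogenous), all standardized to
  unit variance. The structural graph is acyclic; each endogenous variable
  is a linear function of its parents plus a residual that is uncorrelated
  with all causally prior variables.
* Each latent variable is measured by a block of ≥ 2 observed indicators,
  x = λ·(latent) + ε, with uncorrelated uniquenesses (a common factor
  model per block). Every indicator belongs to exactly one block (Mode A,
  reflective).
* Correlations are allowed only between exogenous variables without
  incoming paths; unlisted exogenous pairs are uncorrelated.

`ModelSpec` validates these constraints (cycle detection, block
disjointness, exogeneity of listed correlations) at construction.

## Estimation

### Step 1 — Mode A weights

The classical iterative PLS algorithm on the indicator correlation matrix
R: starting from equal weights, alternate (i) inner proxies, built from
composite correlations via an inner weighting scheme, and (ii) the Mode A
outer update w ∝ cov(x_block, inner proxy), normalizing each block to unit
composite variance w'R_bb w = 1 and fixing signs by positive block weight
sum (ties broken by the first weight's sign). Convergence is max absolute
change in weights < `tol` (default 1e-6, `max_iter` 300).

Inner schemes: `path` (default; regression weights on structural parents,
correlations with children), `centroid` (signs of composite correlations),
`factorial` (composite correlations). The disattenuation step below is
consistent under any of them; on the study's populations the three schemes
agree to well under 0.01 in the weights. A latent variable with no
structural neighbours uses its own composite as inner proxy.

The numeric core runs on moments, accepts a batch dimension (used to
iterate hundreds of bootstrap resamples or CV folds simultaneously), and
has an explicit moments-mode entry point
(`estimate_weights_from_moments`), so populations can be analyzed exactly:
supplying an implied population covariance yields the probability-limit
weights, reliabilities and path estimates without sampling noise.

### Step 2 — reliabilities and disattenuation

The consistent reliability of each block's composite is

    rho_A = (w'w)^2 * w'(S - diag S) w / w'(w w' - diag(w w')) w ,

with S the block's sample covariance (correlation, after standardization).
Estimates outside (0, 1] are *carried with a validity flag*, never clamped;
a value ≤ 0 makes disattenuation undefined and the fit fails. Composite
correlations are corrected entrywise, r*_ij = r_ij / √(rho_i rho_j), the
diagonal reset to 1. The corrected matrix need not be positive definite;
its smallest eigenvalue travels with it (`ConsistentCorrelation`), and
PD means eigmin > 1e-10 throughout the package.

### Step 3 — structural coefficients

Equations are solved independently in topological order. PLSc solves
R_X β = r_Xy per equation and raises `SingularMatrixError` either when the
full disattenuated matrix is not PD (no consistent solution exists) or
when an equation's predictor matrix has reciprocal condition < 1e-12.
RegPLSc solves (R_X + λI) β = r_Xy with λ ≥ 0 per equation; λ = 0
reproduces PLSc exactly.

### Cross-validated λ

The prediction error that CV minimizes is not uniquely pinned down by the
method's description, so the package defines it as honest out-of-sample
structural prediction: within each of K folds, weights, reliabilities and
ridge coefficients are estimated on the training folds only; validation
rows are standardized by training moments and scored with training
weights; the error of a candidate λ is the accumulated squared residual of
each validation composite predicted from its parents' composites via the
training ridge coefficients. λ is selected per endogenous equation
(a global-λ option exists), ties going to the smallest λ (least bias).

Defaults: K = 5 with seeded shuffling, switching to leave-one-out when
N < 40 (no shuffling needed); grid {0} ∪ 30 log-spaced values in
[1e-4, 1], so CV can always fall back to plain PLSc. Training folds whose
moments yield no usable consistent correlations (some rho_A ≤ 0) are
skipped; in the rare event that every fold is unusable the selection falls
back to λ = 0 and records `folds_used = 0`. A training fold that stops at
`max_iter` without meeting the weight tolerance still contributes its last
iterate — CV only ranks candidate λ values and near-fixed-point weights
suffice for that.

### Bootstrap inference

Nonparametric bootstrap over rows: SE = standard deviation of the B
coefficient draws, CI = percentile interval with linear interpolation
between order statistics, significance = CI excludes zero. Default
B = 5000; simulation studies use 200. Two deliberate choices:

* λ is **not** re-selected per resample; it stays at the full-sample CV
  choice, so SEs reflect sampling variability at that tuning rather than
  tuning noise (`reselect_lambda=True` for sensitivity analysis).
* A resample is excluded only when genuinely incomputable: non-convergent
  weights, a constant column, rho_A ≤ 0, or a singular equation system.
  Resamples whose disattenuated matrix is indefinite still contribute —
  their per-equation estimates are finite, and conditioning on positive
  definiteness truncates the bootstrap distribution's tails, which
  measurably biases the intervals (type-I error for a true-zero path
  roughly doubles). More than 50% exclusions raises an error.

The weight sign convention applies inside every resample, preventing sign
flips from inflating SEs. Given a seed, summaries are bit-identical across
runs.

## Synthetic populations and the study harness

The generator reconstructs the six-latent-variable study design: three
exogenous factors (corr(ξ1, ξ2) = φ; ξ3 orthogonal — the only layout
consistent with the printed orthogonal-predictor coefficients
γ21 = γ23 = √(R²/2)), three endogenous ones (η1 ← ξ1, ξ2; η2 ← ξ1, ξ2, ξ3
with the ξ2 path truly zero; η3 ← η1, η2), four reflective indicators per
factor. Within a block all loadings are equal — the minimal assumption
given that only the block's composite reliability is specified — at
λ = √(ρ/(p(1−ρ)+ρ)), the value solving the composite-reliability identity.
Latent correlations follow from the true standardized coefficients by path
tracing (the shipped coefficient table is the authoritative
parameterization; users can substitute their own CSV). The implied
indicator covariance Σ = ΛΦΛ' + Θ has exactly unit diagonal and is checked
PD; samples are N(0, Σ) via Cholesky.

What the generator does **not** emulate: non-normal or ordinal indicators,
unequal loadings within a block, correlated uniquenesses, model
misspecification. A green simulation test therefore certifies estimator
behaviour under a correctly specified normal common factor model, nothing
broader.

Design cells cross N ∈ {30, 60, 120, 200}, φ ∈ {0.4, 0.6, 0.8},
reliability ∈ {0.6, 0.8}, R² ∈ {0.25, 0.50} (48 cells; arbitrary user
levels allowed). Per cell, samples are drawn until the target number of
*proper* replications is reached; a sample is proper iff weight estimation
converged, all rho_A > 0, and the disattenuated matrix is PD. Under weak
reliability, extreme collinearity and small N the improper rate is very
high (a large majority of draws at the hardest cells) — this is a property
of disattenuation, not a bug; discard counts are reported per cell, and a
cell errors out only if fewer than 0.5% of draws are proper after
max(1000, 100·reps) attempts. Both methods are fit to the same proper
samples and share bootstrap resample indices (common random numbers) to
sharpen the paired comparison. Recovery is the mean absolute difference
between the 7 estimated and true standardized coefficients per
replication; power/type-I are CI rejection proportions. Per-cell seeds
spawn deterministically from the master seed.

The harness emits tidy long-format tables (cell × method × path) suitable
for external ANOVA-style analysis; no ANOVA is computed here.

## Numerical conventions

* Standardization always uses divisor N − 1; data are standardized
  internally when not already flagged as such.
* PD threshold: smallest eigenvalue > 1e-10, everywhere.
* Weight tolerance 1e-6, max 300 iterations, all-equal initialization
  (deterministic); batched iteration stops when every batch element has
  converged.
* Singularity in batched per-equation solves degrades to NaN for the
  affected element (then counted as a failure), never an exception that
  aborts the batch.
* Floats in result files carry 6 significant digits; row order is
  deterministic.

## Limitations

* Mode B (formative) blocks, non-recursive graphs and higher-order
  constructs are out of scope and rejected at spec validation.
* rho_A requires ≥ 2 indicators per block; single-indicator constructs are
  not representable.
* The CV error definition above is one defensible reading; other
  definitions (e.g. indicator-level reconstruction error) would select
  somewhat different λ.
* Bootstrap intervals are percentile, not BCa; with B = 200 the tail
  quantiles rest on ~5 order statistics and per-cell rejection rates at
  small replication counts are correspondingly noisy.
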