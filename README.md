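# regplsc — consistent PLS path modeling with ridge regularization

`regplsc` estimates recursive structural equation models with reflective
(Mode A) measurement blocks by **consistent partial least squares (PLSc)**
and by its **ridge-regularized extension (RegPLSc)**, with nonparametric
bootstrap inference and a Monte Carlo harness for parameter-recovery and
power studies.

## The problem and the method

PLS path modeling represents each latent variable η by a weighted composite
of its observed indicators. Composites carry measurement error, so their
correlations *attenuate* the true latent correlations and plain PLS path
coefficients are inconsistent when a common factor model holds. PLSc fixes
this in three steps:

1. **Weights.** Iterative Mode A estimation of indicator weights ŵ per
   block, normalized so each composite has unit variance.
2. **Disattenuation.** The consistent reliability of each composite,

       ρ_A = (ŵ'ŵ)² · ŵ'(S − diag S)ŵ / ŵ'(ŵŵ' − diag(ŵŵ'))ŵ ,

   (S the block covariance matrix) rescales every composite correlation:
   r*_ij = r_ij / √(ρ_A,i · ρ_A,j).
3. **Paths.** Each endogenous latent variable is regressed on its parents
   using the disattenuated correlations: β̂ = R_X⁻¹ r_Xy.

Disattenuation *inflates* correlations, so R_X is often near-singular (or
leaves the positive-definite cone entirely) exactly when latent predictors
are highly correlated — small samples, weak reliability and collinearity
make PLSc estimates explode or fail. RegPLSc replaces the OLS step with a
ridge least squares estimator

    β̂(λ) = (R_X + λI)⁻¹ r_Xy ,    λ ≥ 0,

choosing λ per endogenous equation by K-fold cross-validation (5-fold,
leave-one-out below N = 40; λ = 0 recovers PLSc exactly). Significance is
decided from bootstrap percentile confidence intervals.

## A worked example

```python
from regplsc import DesignCell, build_population, generate_sample, fit, bootstrap

# a population with extreme collinearity (phi = 0.8) and weak measurement
pop = build_population(DesignCell(N=60, phi=0.8, reliability=0.6, r2=0.25))
X = generate_sample(pop, 60, seed=4)

res = fit(X, pop.spec, "regplsc", seed=0)
print(res.paths.lambdas)
# {'eta1': 0.1487, 'eta2': 1.0, 'eta3': 1.0}
print({k: round(v, 3) for k, v in res.paths.coefficients.items()})
# {'gamma11': 0.718, 'gamma12': -0.082, 'gamma21': 0.16,
#  'gamma22': 0.248, 'gamma23': 0.292, 'beta31': 0.335, 'beta32': 0.243}
```

On this sample the disattenuated correlation matrix has smallest eigenvalue
−0.15, so `fit(X, pop.spec, "plsc")` raises `SingularMatrixError` — there is
no consistent OLS solution — while the ridge route returns finite, bounded
estimates (true values: 0.281, 0.246, 0.354, 0, 0.354, 0.391, 0.311). The
cross-validation chose heavy shrinkage (λ = 1) for the two equations whose
predictors are most collinear. `bootstrap(...)` adds percentile confidence
intervals and per-path significance decisions.

The `examples/` directory holds one short script per capability
(population identities, single-dataset fits, bootstrap inference, a
scaled-down simulation slice, the CSV/JSON file workflow); each prints the
numbers it computes and a line on what they mean.

## The Monte Carlo harness

`run_study` reconstructs a 48-cell factorial design — sample size N ∈
{30, 60, 120, 200}, exogenous collinearity φ ∈ {0.4, 0.6, 0.8}, composite
reliability ∈ {0.6, 0.8}, R² ∈ {0.25, 0.50} — over a six-latent-variable
population (four reflective indicators each; one structural path is truly
zero). Per cell it draws multivariate normal samples, discards improper
ones (non-positive-definite disattenuated correlation matrix), fits both
estimators to the same samples, and aggregates mean absolute differences
(MAD) to the true coefficients plus bootstrap rejection rates (power and
type-I error).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch (about 10 minutes on one
CPU): the analytic population identities (equal loading, population
weights, ρ_A at exact moments, design-grid size), the orthogonal-predictor
coefficients solving 2c² = R², the grand-mean MAD of both estimators over
the 48-cell design at 100 replications per cell, and the rejection rates
for the true-zero path over the N=60 cells at 100 replications × 200
bootstrap resamples. Results are written as JSON keyed by quantity id;
`--reps`/`--bootstrap` scale the studies up or down.
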