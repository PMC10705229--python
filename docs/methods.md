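# Methods

## The measurement-error model

The package treats a polygenic risk score `Z_p` as a calibrated but noisy
measurement of a latent covariate `Z`:

    Z_p | Z ~ N(a Z, τ²),   Z ~ N(0, 1).

`a` is the calibration slope of `Z_p` on `Z` (not the reverse; the
estimator refuses swapped inputs rather than silently transposing them)
and `τ²` the residual variance. Both are estimated by least squares on a
validation set of `S ≥ 3` pairs, with both columns centered first so the
no-intercept regression is exact, and denominator `S − 1` for the residual
variance (one slope parameter after centering; exposed as `ddof` since the
choice is `O(1/S)`). The validation `Z` may optionally be standardized to
match the test-set convention, but `Z_p` is never rescaled inside the
estimator: `a` and `τ²` are only meaningful if the PRS means the same
thing in validation and test data, so any standardizer for `Z_p` must be
shared between the two — the CLI keeps the PRS column untouched for this
reason.

The *reliability* of the PRS is reported as the squared correlation
`a²/(a² + τ²)` (under `Var(Z) = 1`). Some texts define the reliability
ratio as a variance ratio in the opposite direction; the squared
correlation form is used here because it is scale-invariant, bounded in
[0, 1], and is exactly the factor-of-interest in the linear attenuation
formula: the naive slope on `Z_p` converges to `γ · a/(a² + τ²)`.

Outcomes follow a linear model `Y = Wα + Zγ + ε`, `ε ~ N(0, σ²)`, or a
logistic model on the log-odds scale. Priors are `α, γ ~ N(0, 10²)` and
`σ ~ half-Cauchy(5)` — read as standard deviations, the Stan convention
for weakly informative scales on standardized data; both are exposed in
`PriorSpec`. The linear model carries no intercept (it presumes a
centered outcome), while the logistic model includes a free intercept
with the same `N(0, coef_scale²)` prior, because a binary outcome cannot
be centered and omitting it biases every fit with case fraction ≠ 1/2.

Degenerate calibration (`τ² = 0`, a perfect PRS) makes the measurement
density improper; `MeasurementModel.floored()` floors `τ²` at
`1e-8 × Var(Z_p)` with a warning, which collapses the latent covariate
onto `Z_p/a` and reduces the corrected fit to ordinary regression — the
behaviour the no-noise tests assert.

## Samplers

The posterior `p(Z, α, γ, σ | Z_p, Y)` is sampled natively rather than
through an external PPL; the conjugate structure makes this both exact in
its conditionals and fast.

**Linear (blocked Gibbs).** Each latent `Z_i` is conditionally Gaussian
with precision `a²/τ² + γ²/σ² + 1` and matching mean; `(α, γ)` is a joint
Gaussian conjugate update given `Z`; `σ` is updated by univariate slice
sampling (stepping-out, width 1 on the log scale) of its half-Cauchy-prior
conditional.

**Logistic (adaptive Metropolis, default).** Latent `Z_i` are updated by
independent per-observation Gaussian-proposal Metropolis steps —
vectorized, since the conditionals are independent given the
coefficients — and the coefficients `(c, α, γ)` by per-coordinate random
walks. Proposal scales adapt in blocks of 50 iterations during warmup
only, targeting acceptance 0.44 per coordinate, and are frozen afterward
to preserve detailed balance.

**Logistic (Pólya-Gamma, optional).** With `algorithm="pg_logistic"` the
Bernoulli likelihood is augmented with PG(1, η) variables, making both the
coefficient block and the latent covariate conditionally Gaussian — a full
Gibbs sweep. The PG draws use the truncated infinite-convolution
representation (128 scaled-exponential terms); the truncation bias is
O(1/K) and the resulting posterior agrees with the exact Metropolis
sampler within Monte-Carlo error in the tests, but the Metropolis
algorithm remains the default because it is exact.

Initialization is the naive least-squares fit of `Y` on `[1, W, Z_p/â]`
(a clipped-logit working response for binary outcomes), `σ` at the
residual SD, and `Z` at `Z_p/â`; any fixed rule is acceptable given the
diagnostics, this one merely shortens warmup. Chains are seeded through
`numpy.random.SeedSequence.spawn`, so runs are bitwise reproducible given
the seed, and a non-finite draw aborts with the chain/iteration reported.

Defaults follow the 4-chain, 2000-iterations-per-chain protocol with 1000
warmup (4000 kept draws). Summaries pool chains: posterior mean, 2.5% and
97.5% empirical quantiles, split-R̂ and rank-normalized bulk ESS (via
arviz). R̂ > 1.01 warns rather than fails — there is no universally agreed
hard threshold and the replicate harness must keep running on occasional
slow-mixing cells. Latent-covariate draws are not stored by default; only
per-observation posterior means and SDs are kept, since `N × 4000` draws
are rarely wanted.

## Synthetic data

**Latent tier** draws exactly from the assumed model: `Z ~ N(0,1)`,
`Z_p = aZ + e`, linear `Y = Zγ + N(0,1)` or logistic
`Y ~ Ber(expit(Zγ))`, with validation pairs drawn independently from the
same law. Defaults are `n_test = n_validation = 2000`, `a = 1`, `τ² = 1`
(reliability 0.5) — a moderate-accuracy PRS at biobank-subsample size, and
the conditions under which the coverage results are computed.

**Genotype tier** makes the Gaussian error model emergent rather than
assumed: allele frequencies uniform on [0.05, 0.5], genotypes
Binomial(2, f) at 1,000 independent SNPs, spike-and-slab causal effects
`β_j ~ π N(0, h²/(Mπ)) + (1−π) δ₀` with `h² = 0.5`, `π = 0.01`,
environmental noise scaled so the realized genetic-variance fraction
equals `h²`, marginal GWAS betas estimated in a 2,000-individual training
set, and scoring weights shrunk by the ridge-style factor
`n_train/(n_train + M/h²)` (`M/h²` being the effective dimension of an
infinitesimal architecture). The genotype standardizer is frozen on the
training set and re-applied downstream to prevent leakage. Realized
`(a, τ²)` are estimated on the validation set and returned, so nothing
downstream assumes nominal values. What this tier does *not* emulate:
linkage disequilibrium, ancestry structure, and the Bayesian
nonparametric PRS weighting used on real biobank genotypes — so realized
reliabilities here (~0.2 at desk defaults) are lower than a well-powered
real PRS, and passing tests speak to the measurement-error structure, not
to any particular trait's attainable accuracy.

## Evaluation harness

For each true effect on a grid of 50 equally spaced values in
[−0.5, 0.5] excluding zero (one replicate per value by default, as in the
two-row error/coverage summary layout), the harness simulates a dataset,
calibrates on the validation pairs, and runs three strategies: *oracle*
(regression on the true covariate), *naive* (regression on the PRS), and
*corrected* (the Bayesian model). Per-cell seeds derive deterministically
from the base seed. "Point estimate error" is `|estimate − γ|` averaged
over cells; coverage is the fraction of 95% intervals containing the
truth. Single-cell failures are excluded with a logged count and more
than 10% failures aborts. Inside the grid the MCMC default is scaled to
2 chains × (500 warmup + 500 kept), overridable to the full protocol; the
error-versus-γ curve routine also reports the fitted slope of signed
error on γ, which is ≈ `reliability − 1` for the naive strategy and ≈ 0
for the corrected one.

Baseline fits use statsmodels (OLS / Newton ML) with Wald 95% intervals —
the default behaviour of standard regression software — and perfect
separation in logistic fits warns and falls back to capped quasi-Newton
iterations instead of failing.

## Numerical and testing choices

* Problem sizes: the test suite and the reproduction script use
  n = 10,000 for the no-error baselines, n = 2,000 with 2 × (1000 + 1000)
  chains for the coverage grids, and 50 replicates per effect value at
  n = 500 for the bias checks — sizes chosen so every law being tested
  (folded-normal baseline error, nominal coverage, unbiasedness within
  Monte-Carlo error) is already in its asymptotic regime.
* Sampler correctness is established on ≤ 6-observation instances against
  two independent routes: dense-grid integration with the latent
  covariate marginalized analytically (linear; each `(Y, Z_p)` pair is
  bivariate normal given `γ, σ`) and prior-weighted importance sampling
  with exact measurement-conditional proposals for the latent covariate
  (logistic, ESS-checked).
* Binary outcomes must be coded 0/1; anything else is refused, never
  coerced. Tables are delimited text with named headers; every output
  file carries the package version, seed, and a hash of the resolved
  configuration in a comment header.

## Known limitations

* `(â, τ̂²)` are plugged in as point estimates; their sampling
  uncertainty is not propagated into the posterior (with `S` in the
  thousands this is second-order, but for very small validation sets the
  intervals will be slightly anticonservative).
* One noisy covariate only; no interactions, no non-Gaussian or
  heteroscedastic measurement error, no Student-t variants.
* The correction restores unbiasedness and interval coverage but cannot
  restore the power lost to PRS noise, and offers little improvement when
  the true effect is near zero.
* Logistic attenuation has no exact closed form; the attenuation-factor
  identities are linear-family results and the logistic analogues are
  tested qualitatively.
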