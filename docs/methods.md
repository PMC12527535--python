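# Methods

## Estimands and identification

The data are individual-participant records pooled from `m` sources:
outcome `Y` (continuous or binary), source label `S`, treatment
`A ∈ {0,1}`, covariates `X`, and optionally a categorical effect modifier
`EM` with `K` levels (kept out of `X` and appended to the design matrix
separately). An external-target analysis adds `n₀` covariate-only rows from
the target population.

Estimands are differences of counterfactual means `E[Y¹ − Y⁰]` in a target
population: each source's underlying population (internal), or the external
population; subgroup effects condition additionally on an `EM` level.
Identification assumes, within each source, consistency, exchangeability
over treatment, and treatment positivity; and across sources,
exchangeability of the potential-outcome distribution given `(X, EM)`. The
last condition licenses pooling the outcome regression over sources and is
not empirically verifiable; the software can only flag practical positivity
problems (it warns when a source × arm (× subgroup) cell has fewer than 10
observations).

## The augmented estimator and its influence function

For target `s`, arm `a` (and optionally subgroup `k`), with
`T_i = 1(S_i = s)[1(EM_i = k)]` and
`W_i = 1(A_i = a) η̂_s(X_i)/ê_a(X_i, S_i) [1(EM_i = k)]`:

```
μ̂ = [ Σ T_i ĝ_a(X_i) + Σ W_i (Y_i − ĝ_a(X_i)) ] / Σ T_i
φ̂_i = (n / Σ T) · [ T_i (ĝ_a(X_i) − μ̂) + W_i (Y_i − ĝ_a(X_i)) ]
```

External targets index the stacked `N + n₀` rows, `T_i` marks external
rows, and `W_i` replaces `η̂_s` with the membership odds `q̂/(1 − q̂)`.
The residual (augmentation) term deliberately pools observations from all
sources, re-weighted to the target's covariate distribution; a
`target_only` variant restricting it to the target source is available as a
diagnostic, not as a primary path. The normalizer is the *realized* target
count (Hájek form), so the empirical mean of `φ̂` is zero by construction —
the estimator literally solves its estimating equation, and the test suite
asserts the residual is below 1e-10. The influence-function second moment
gives `se = sqrt(mean(φ̂²)/n)` with `n` the full index length (`N` internal,
`N + n₀` external). The exact normalized form of the influence function is
this package's own construction (standard for Hájek-normalized augmented
estimators); it is validated against an exhaustive-enumeration oracle on
discrete data and against the bootstrap.

With exact empirical-frequency nuisances on discrete data the augmentation
vanishes and the estimator reduces to the identification plug-in; note the
pooled frequency outcome model that achieves this exactly is the
inverse-propensity-weighted cell mean `Σ_s n_{x,s} ȳ(x,s,a) / n_x`, i.e.
the empirical solution of the pooled weighted estimating equation — the
tests construct it explicitly.

## Nuisance estimation

Four nuisance functions: outcome `g_a(x)` (fit per arm, pooled over
sources, features `X` + `EM` indicators), source `η_s(x)` (multinomial
logistic regression, optionally penalized with a CV-chosen penalty, or a
single-hidden-layer network; `η ≡ 1` when `m = 1`), propensity `e_a(x, s)`
(one joint fit with source indicators, or one fit per source), and — for
external analyses — membership `q(x)` fit on the stacked rows.

Outcome, treatment and external models go through a cross-validated super
learner: V-fold (default 10, stratified by class for binary labels)
out-of-fold predictions per candidate learner; `stack` mode solves for
simplex weights minimizing CV squared error (continuous) or Bernoulli
negative log-likelihood (binary), `select` mode puts weight 1 on the
CV-best candidate. The simplex problem is solved by SLSQP started at the
best single learner's vertex, falling back to that vertex if the optimizer
fails to improve it — this guarantees the stacked CV risk never exceeds the
best single learner's, an invariant the tests assert. A learner that fails
to fit is dropped with a warning; only total failure is an error.
Single-learner libraries short-circuit (weight 1, no CV). Learners are
scikit-learn estimators behind a string registry; custom learners register
programmatically.

Estimated probabilities (`η̂`, `ê`, `q̂`) are clipped into `[ε, 1 − ε]`,
default `ε = 0.01`, with clip counts logged. `η̂` rows sum to 1 before
clipping by construction. Continuous covariates are used as-is by default;
a `standardize` flag (off by default) centers and scales them with moments
learned on the multi-source data. Categorical covariates are encoded as
reference-dropped indicators with lexicographically sorted levels, so the
design matrix is deterministic across runs; an external row with an unseen
level is a hard error, never silently zeroed. Missing values are rejected,
not imputed.

## Cross-fitting

When enabled, each replication splits the data into `J` folds stratified by
source (source × subgroup for STE analyses; external rows form their own
stratum), `J = 4` internal and `5` external. The estimation fold rotates
through all `J` positions; in each cycle the remaining folds are assigned
one-per-nuisance by a fixed cyclic rotation, so over a replication every
fold plays every role exactly once. The per-row nuisance predictions used
in the estimating equation always come from models fit without that row's
fold (no leakage; the rotation structure is unit-tested). Replication
estimates are pooled-estimating-equation solutions; across `R` replications
(default 100, recommended for split-insensitive results) the point estimate
is the mean and the variance is
`mean_r(var_r) + mean_r((est_r − mean)²)` — the between-replication term
guards against split sensitivity. The master seed spawns per-replication
seeds via `numpy` `SeedSequence`, so reruns are bit-identical and any single
replication is reproducible. Cross-fitting is discouraged (a warning) when
a stratum cannot populate its folds, and fitted working models are not
retained across replications — the model report is only available from
non-cross-fit runs.

## Simultaneous confidence bands

For the `K` subgroup effects of one target population, the band is sup-t:
estimate the covariance of the estimates from the influence-function
columns (`Σ̂_jk = mean(φ_j φ_k)/n`), form its correlation matrix (repairing
indefiniteness by flooring eigenvalues at 1e-10, flagged), draw the
level-quantile of `max_j |Z_j|` for `Z ~ N(0, corr)` by Monte Carlo
(default 10,000 seeded draws), and set `estimate ± c·se`. Because
`c ≥ z_{(1+level)/2}`, the band always contains the pointwise CIs. `K = 1`
reduces to the Wald CI; two independent subgroups reproduce the Šidák value
2.2365. Bands are per target population only; joint uncertainty across
target populations is out of scope. Under cross-fitting the band is rebuilt
from the aggregated covariance.

## Synthetic studies

The generator emulates the structure the estimators target: per-source
Gaussian covariates with population-specific mean shifts (case-mix
differences), per-population subgroup frequencies, source-specific logistic
propensities clamped into `[0.02, 0.98]` (positivity by construction), and
a linear-Gaussian — or logistic, for binary outcomes — potential-outcome
model with a treatment main effect and treatment × subgroup
(and optionally treatment × covariate) interactions. Both potential
outcomes are generated per row (sharing one noise draw) and the realized
treatment reveals one, so consistency holds exactly and the hidden pair
supports oracle checks. Default dimensions are three sources of
2312/1147/592, an external population of 10,083, nine continuous
covariates, and a five-level effect modifier — a typical multi-source IPD
shape. Truth comes from Monte Carlo integration over each target
population's covariate law, with closed forms for the identity link exposed
as an independent oracle.

What the generator does *not* emulate: non-Gaussian or dependent
covariates, measurement error, missingness, censoring, and outcome models
outside the (generalized) linear family. Passing tests therefore show
correctness of the estimation machinery under its stated assumptions, not
robustness to violations of them.

## Validation study sizes

The statistical test suite uses: double robustness — two sources of 2,500
plus 2,500 external rows, 200 replications, with arms in which only the
outcome model, only the weight models, or none are correctly specified
(the half-correct arms must be within 3 Monte-Carlo SEs of truth; the
all-wrong arm must not be); coverage — a 3,000-row three-source study with
2,000 external rows and five subgroups, 300 replications, pointwise 95% CI
coverage required in [0.92, 0.975] and simultaneous band coverage in
[0.91, 0.98] and at least the all-subgroups CI coverage; bootstrap
agreement — 500 resamples at n = 2,000, within 15% of the IF-based SE.
These sizes were chosen so each study's Monte-Carlo error is small relative
to the property being asserted.

## Known limitations

Binary treatments only; difference-scale effects only (no risk or odds
ratios); categorical effect modifiers only; no missing-data handling; no
survival outcomes; single-process execution. The reference-level one-hot
encoding assumes the multi-source data exhibit every level the external
data will present.
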