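# Methods

## Model

Each person contributes three phenotype sum scores; the canonical order is
(aggression, hyperactivity, inattention), outcome first.  Conditional on sex
and age, the 3×3 phenotypic covariance is decomposed as

    Σ_ph = Σ_A + Σ_C + Σ_D + Σ_E        (children; adults: Σ_A + Σ_D + Σ_E)

where A is additive genetic, D dominance (non-additive genetic), C common
(twin-shared) environment, and E unique environment.  Each component is
Σ_x = Λ_x Λ_xᵗ with Λ_x lower-triangular, so every iterate of the optimizer
is positive semi-definite without penalties.  Twin pairs are 6-variate
normal with within-person blocks Σ_ph and cross-twin blocks

    MZ: Σ_A + Σ_C + Σ_D        DZ: 0.5·Σ_A + Σ_C + 0.25·Σ_D ,

the 0.5/0.25 weights being the expected sharing of additive and dominance
effects in dizygotic twins.  Opposite-sex DZ pairs are pooled with same-sex
DZ pairs (no sex-limitation model).

**Identification.**  With MZ/DZ data a free ADCE model is not identified.
The children's model is identified by structure: Λ_C has only its first
column free (one environmental factor shared by all three traits, so Σ_C has
rank ≤ 1) and Λ_D has the outcome row and column fixed to zero (dominance
confined to the two predictors, rank ≤ 2).  Adults carry no C; A, D, E are
full Cholesky factors.  Diagonal factor cells are constrained non-negative
to resolve the column-sign indeterminacy of Λ Λᵗ.

**Means.**  Per phenotype an intercept, a sex effect (0 = male, 1 = female)
and an age effect (years, uncentered; centering only shifts the intercept).
Both twins share the age; each uses their own sex.

## Estimation

**FIML.**  Each pair contributes the log-density of its *observed* phenotype
subvector under the implied mean and covariance — no imputation; pairs with
all six slots missing are dropped with a logged count.  Records are grouped
by (zygosity, missingness pattern) and evaluated vectorized.  The gradient
is analytic: with subvector precision P, record count n, and residual
cross-product M, ∂ℓ/∂S = −(nP − PMP)/2, scattered to 6×6 position and
chained through the cross-twin weights and ∂Σ_x/∂λ_ij = E_ij Λᵗ + Λ E_ijᵗ;
mean derivatives use ∂ℓ/∂μ = P r.  Optimization is L-BFGS-B from 5 jittered
starts (seeded; single-start is an explicit option for large well-behaved
problems).  Starting values split the pooled within-person sample covariance
equally across the k components present (target S/k per component, which is
positive definite whenever S is and hence factorizable under every pattern),
with means started at phenotype means.

**Convergence.**  Optimizer success plus a gradient criterion of
‖g‖∞ ≤ 1e−5·max(1, |ℓ|).  The relative form reflects that the attainable
gradient scale grows with the magnitude of the log-likelihood; a fit that
misses it is returned flagged `converged=False` with full diagnostics.

**Moment mode.**  When only MZ/DZ summary tables are available, the model is
fitted by minimizing the normal-theory discrepancy
Σ_g n_g·[ln|Σ_g(θ)| + tr(S_g Σ_g(θ)⁻¹) − ln|S_g| − 6], which is zero iff
both sample matrices are reproduced exactly.  Correlation + SD tables are
converted by S = D·R·D with symmetry enforced by averaging.

**Uncertainty.**  The observed information is computed by central
differences of the analytic gradient; its inverse gives Wald SEs, and
delta-method SEs for any differentiable derived quantity (standardized
shares, covariance-level regression coefficients) via a numerical Jacobian.
When a fit sits on the PSD boundary (e.g. a Cholesky diagonal at zero, as
happens when the generating additive matrix is nearly rank 1) the
information matrix is singular; intervals are then reported as undefined and
flagged, never fabricated.  Profile-likelihood intervals for raw parameters
are available by re-optimizing with the parameter fixed and inverting the
likelihood-ratio statistic.

## Covariance-level regression

At level Σ ∈ {Σ_ph, Σ_G = Σ_A + Σ_D, Σ_T = Σ_C + Σ_E} the regression is the
population solve b = Σ₂⁻¹Σ₁ on the predictor block.  The decomposition

    s²_out = b₁²s₁² + b₂²s₂² + 2b₁b₂s₁₂ + s²_ε

holds exactly by construction and is enforced to 1e−10 relative; the cross
term is reported separately because it cannot be attributed to either
predictor.  Shares can be standardized by the level variance or the
phenotypic variance; the two differ by the factor (level outcome variance /
phenotypic outcome variance), so G- and T-level phenotypic shares add up to
the phenotypic regression's explained variance.

The predictor block must be positive definite with condition number below
1e8; otherwise the solve is refused with the offending eigenvalues rather
than regularized — this is what rules out regression on the structured C
(rank-1) matrix, and on any nearly rank-1 additive matrix, and is why the
analysis levels are G and T.  A dominance matrix with outcome row zero
passes the guard but returns b = 0 (the outcome simply carries no dominance
variance).  Explained-variance totals are always the additive sum of the
three components; `check_claimed_total` compares such a sum against an
externally claimed total and flags inconsistencies (the shipped adult
environmental table is a live example: its published total, 16.4%, exceeds
the sum of its own published components, 9.3%, and the package reports the
additive 9.4% with a flag).

## Phenotypic regression

The within-person model Agg = b₀ + b_Sex·Sex + b_Age·Age + b_HA·HA +
b_InA·InA + ε is fitted by ML on pairs with one coefficient vector shared
across zygosity and birth order, and the two outcome residuals of a pair
bivariate normal with a cross-twin covariance estimated freely per zygosity
(|cov| < s²_ε via a tanh parameterization).  A twin contributes an outcome
equation only when their outcome and both predictors are observed; the
co-twin's equation is kept (partial-pair likelihood, conditional on observed
predictors).  With both cross-twin covariances constrained to zero the
estimates coincide with pooled individual-level least squares, which the
tests verify.  The explained-variance decomposition uses the predictor
covariance conditional on sex and age (each phenotype residualized on
[1, sex, age], covariance assembled pairwise-complete).

Checklist sum scores are simple sums of observed items with a per-scale
missing-item allowance (3 for the 18- and 15-item aggression scales, 1 per
6-item child ADHD subscale, 2 per 9-item adult subscale) and no proration;
exceeding the allowance yields a missing score.

## Synthetic data

The generator draws pairs from the exact 6-variate normal implied by the
component matrices, with sexes Bernoulli (optionally a fixed opposite-sex
fraction among DZ pairs), a shared normal age, and the fixed-effect means.
Missingness is completely at random per cell by default; an optional block
pattern removes the predictor scales for a random subset of pairs entirely,
emulating instruments introduced part-way through a study — FIML is
consistent under both.  The shipped study configurations use the published
component and mean estimates with the study pair counts (4,209 MZ + 7,136 DZ
children, age 9.94 ± 0.51; 3,438 MZ + 3,995 DZ adults, age 29.8 ± 12.5).

What the generator deliberately does not emulate: real checklist scores are
bounded, discrete, and right-skewed, and real missingness need not be
ignorable.  Passing recovery tests therefore demonstrates correctness of the
estimator under the model's own assumptions, not robustness to
non-normality.

## Numerical choices and conventions

- PSD tolerance for factor-built matrices: smallest eigenvalue ≥
  −1e−8·(leading).  Matrices transcribed from rounded published tables use
  a transcription tolerance of 1e−2 relative (entries printed to ~3
  significant figures perturb eigenvalues by up to about that fraction of
  the leading one); the same tolerance is the near-rank cut for diagnosing
  an almost-singular component.  The strict rank tolerance default is 1e−9.
- The shipped children unique-environment matrix resolves an internal
  inconsistency of its source table: the printed aggression–inattention
  covariance (1.28) disagrees with the printed correlation (0.258 ⇒ ≈1.12);
  the correlation-implied value is used because only it reproduces the
  published downstream regression results.
- L-BFGS-B with ftol 1e−11 and a scaled projected-gradient tolerance;
  multistart jitter is multiplicative 10% plus additive 0.01, seeded.
- Wald intervals are the default for derived quantities; profile intervals
  are opt-in per parameter.
- Problem sizes in the test suite: parameter recovery uses 5,000 + 5,000
  pairs with the error averaged over 3 replicates (separating estimator
  bias from single-draw noise); moment-convergence checks use up to 50,000
  pairs; the end-to-end pipeline demonstration uses 2,000 pairs.

## Known limitations

- No sex-limitation models (opposite-sex DZ pairs are pooled), no ordinal
  liability-threshold models, no robust/sandwich SEs, and no more than two
  predictors (the algebra generalizes; the tested surface does not).
- The adult cohort's two measurement occasions (predictors assessed years
  before the outcome) are not modelled longitudinally.
- Moderation of the regression by continuous covariates (e.g. age) is out
  of scope.
- Standardized-share labels follow the component matrices; where a published
  standardized table disagrees with its own matrices (transposed-looking
  predictor columns in the children block), the package reports the
  matrix-implied shares by phenotype label and does not attempt to resolve
  the table.
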