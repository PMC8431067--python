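# Methods

This note documents the statistical model the package implements, the choices
made where the method leaves room, the synthetic data-generating process and
what it does and does not emulate, and the problem sizes used by the test
suite. Nothing here reports an empirical number that the tests or
`scripts/acceptance.py` do not themselves compute.

## Indices

**Fractional ranks.** Economic position is the weighted fractional rank of
equivalized income: after sorting ascending, unit *i* gets
`r_i = (W_below + w_i/2) / W_total`. Tied incomes form one block and share the
block's weight-span midpoint, so ranks are invariant to input order — an
order-dependent tie-break would make bootstrap replicates irreproducible.
This construction gives weighted mean exactly ½ for any weights, and ranks are
invariant under any strictly increasing transform of income. Ranks are
computed within each group (country), since all analyses are per-country.
Income is equivalized by the single-parameter scale `income / hh_size^θ`; the
power θ defaults to 0.5 (the conventional square-root scale) and is
configurable, since only the scale family, not θ, is pinned down by common
practice.

**Concentration indices.** The standard index is implemented in its
covariance form `CI = 2 cov_w(y, r) / ȳ` (weights normalized), the Erreygers
correction as `CCI = 4 ȳ CI = 8 cov_w(y, r)`, and the generalized index as
`GCI = 2 cov_w(v, r)`. The covariance form is used deliberately: sum-based
textbook formulas without rank demeaning evaluate to nonzero for a constant
outcome, whereas the covariance form satisfies CI(constant) = 0, the bounds
`CI ∈ [ȳ−1, 1−ȳ]` for binary outcomes, and `CCI ∈ [−1, 1]`, which is what
the verbal definition (twice the area between the concentration curve and the
45° line) requires. A degenerate binary outcome (prevalence 0 or 1) raises an
explicit error rather than returning a silent 0.

**Analytic standard errors.** Via the convenient-regression device: a scaled
transform of `y` (e.g. `8 var_w(r) · y_i` for the CCI) is regressed on the
rank by weighted least squares, so the slope equals the index, and the SE is
the heteroskedasticity-robust sandwich of the slope. Conventions: weights
enter the meat squared (the survey/pweight convention, appropriate for
calibrated cross-sectional weights), with an HC1-type `n/(n−2)` small-sample
factor; weights are normalized to sum to *n* so results are invariant to
weight rescaling. With equal weights this reproduces textbook OLS-HC1 exactly
(verified against statsmodels in the tests). Clustering and stratification
beyond weights are not modelled.

## Probit engine

Outcomes are binary, so the outcome model is a survey-weighted probit fitted
by Fisher-scoring Newton iterations with step-halving on likelihood decrease
and a 1e-8 ridge fallback for near-singular information matrices.
Convergence: gradient max-norm < 1e-8 or relative log-likelihood change
< 1e-10, max 100 iterations. The variance is the sandwich (expected
information bread, squared-weight score meat). Perfect separation is detected
by a diverging linear index with a non-vanishing gradient and reported with
the most suspect regressor; rank-deficient designs raise a collinearity error
naming aliased columns. Categorical regressors expand to dummies against
fixed first-listed reference categories (age 50–64, SAH excellent/very good,
primary education, inactive).

Downstream linearization uses **partial effects at the weighted sample
means**, `m_j = φ(x̄'β̂) β̂_j` — not average partial effects — because the
decomposition needs a single linear representation of the fitted probability
around the sample means.

## Decomposition and HI

Given slopes `m_j` (probit partial effects at means, or WLS coefficients in
the `ols` mode), each regressor contributes
`4 m_j x̄_j CI(x_j) = 8 m_j cov_w(x_j, r)` on the Erreygers scale, and the
residual term is `4 GCI(u) = 8 cov_w(u, r)` with
`u = y − (α_m + Σ_j m_j x_j)` (the constant chosen so `u` has zero weighted
mean; it does not affect any covariance). Because covariance is linear, the
adding-up identity `CCI = Σ contributions + residual` holds to machine
precision for both modes; for the probit mode the residual additionally
carries the linear-approximation error and is always reported. Contributions
are computed on the Erreygers scale throughout (the algebraic consequence of
`CCI = 4ȳ·CI` applied to the linear decomposition), which is what makes the
identity exact; per-factor roll-ups of dummy contributions are provided for
readability. The intercept contributes nothing (CI of a constant is 0).

`HI = CCI − Σ_{j∈need} contribution_j`. With no need variables, HI = CCI
identically. An alternative HI via indirect standardization (CCI of the
outcome minus the Erreygers-scale index of the need-predicted probability
with non-need variables at their means) is provided as a cross-check; the two
agree up to linearization error and the subtraction-of-contributions form is
the default.

## Inference

The CCI gets normal-approximation inference from its analytic robust SE. HI
standard errors and intervals come from a nonparametric bootstrap (default
1000 replications): individuals are resampled with replacement within the
group, weights travelling with their rows, and the *entire* chain — ranks,
probit, decomposition — is recomputed per replicate, because the rank is part
of the estimator. Intervals are bias-corrected percentile (BC, not BCa:
acceleration would need a jackknife that adds little for these sample sizes):
`z0 = Φ⁻¹(fraction of replicates below the point estimate)` (clipped to
(1/(B+1), B/(B+1)) in degenerate cases), endpoints at bootstrap quantiles
`Φ(2 z0 ± z_{α/2})`. When the point estimate sits at the bootstrap median the
BC interval equals the plain percentile interval exactly. Replicates that
fail (degenerate resampled outcome, separation) are dropped and counted;
a failure share above 5% flags the result unreliable rather than crashing —
small countries plausibly produce occasional degenerate resamples. Multiple
confidence levels are read off one replicate set. Stars follow the two-sided
convention * p<0.1, ** p<0.05, *** p<0.01, using the normal approximation
with the bootstrap SE for HI.

The batch runner derives per-group bootstrap seeds from the master seed and a
CRC of the group label, so adding a country never perturbs another country's
results, and any failing group becomes an NA row with a reason string.

## Synthetic data-generating process

The generator emulates a pooled European 50+ survey extract. Parameters were
chosen once to sit near the published pooled descriptive statistics and are
the package's fixed study conditions:

- household income lognormal (location 9.81, scale 0.77 on the log scale ≈
  mean equivalized income 18.7k with coefficient of variation ~0.9);
  household size on {1..5} with P(1) = 0.28 (living alone is defined as
  household size 1); weights uniform on [0.5, 1.5];
- age drawn by band with the published band shares (mean ≈ 67.8), female
  share 0.546;
- self-assessed health from an ordered latent index `0.45 z_age − 0.35 z_inc
  + N(0,1)` cut to match the pooled category shares — this is the main
  channel tying need to income, which HI testing requires; worsened health
  probit-linked to SAH (marginal ≈ 0.093); chronic count Poisson with
  age-linked log-mean (mean ≈ 1.8); cancer 0.037; ADL/IADL zero-inflated
  counts with age-linked positivity (means ≈ 0.18 / 0.34);
- education from an income-linked ordered latent (slope 0.8), job situation
  age-dependent, urban 0.62;
- outcomes from `y* = α + x'β + z'γ + δ·(ln eq income − center) + ε`,
  ε standard normal (a logistic toggle exists for misspecification
  experiments). The centering constant is the exact config-implied mean of
  log equivalized income, so δ moves inequity, not prevalence. Need slopes
  are a moderate morbidity gradient (SAH poor +0.40, cancer +0.30, chronic
  +0.08 per condition, …).

Preset scenarios: `share_like` (non-need effects on, δ = 0, prevalences
0.2533 / 0.0540), `null_need_only` (γ = 0, δ = 0: true HI = 0),
`pro_rich_denial` (δ = −0.25 on denied care), `pro_poor_postponement`
(δ = +0.12 on postponed care). Intercepts were calibrated once by bisection
against the target prevalences at 500k draws and frozen in the source.

What the generator does **not** emulate: the survey's sampling design
(clustering, strata, calibration), item non-response and income imputation,
per-country heterogeneity in prevalences and income distributions (all groups
share the pooled parameters unless configured otherwise), and any
misreporting/recall structure. Passing tests therefore demonstrate that the
estimator chain recovers known inequity structure under a correctly specified
probit with realistic marginals — not that it is robust to design features
real extracts may carry.

## Problem sizes used in testing

The Monte-Carlo checks run at deliberately scaled sizes: null-coverage uses
200 trials of n = 2000 with 200 bootstrap replicates (95% BC interval covers
zero in ≥ 90% of trials); sign recovery uses 50 trials of n = 20,000 with 200
replicates (≥ 80% detection); the null-HI and sign consistency checks of the
decomposition alone use 200 replicates at n = 20,000. Production analyses
should use the default 1000 bootstrap replications.

## Known limitations

- The probit linearization leaves an approximation error in the residual
  term; with strongly income-graded need and a very nonlinear response it can
  shift HI slightly (visible as a small mean offset in the null scenario,
  well inside the bootstrap noise at the tested sizes).
- Robust SEs are weight-aware but design-naive (no clustering/strata).
- HI inherits the usual caveat of need standardization: need not captured by
  the observed regressors but correlated with income biases HI.
- The bundled published table reproduces printed estimate/SE/star triples;
  for three denied-care concentration-index entries (Italy, Greece, Poland)
  the printed stars are inconsistent with their own printed estimate/SE pairs
  under any single two-sided normal threshold rule, so exact star
  reproduction fails for those three cells (and only those) by construction.
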