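# Methods

## The model

Each effect size is one study-specific record of at-vessel mortality (AVM)
for one elasmobranch species: `x_i` animals dead at haulback out of `n_i`
caught on pelagic longline gear. The core model is a binomial-Normal
hierarchical (multilevel) meta-regression fit by MCMC:

```
x_i ~ Binomial(n_i, p_i)
logit(p_i) = b0 + X_i' beta + f(z_i)
             + u_phylo[species_i] + u_study[study_i] + u_record[i] + u_group[rg_i]

u_phylo ~ MVN(0, sigma_phylo^2 * C)
u_study[s] ~ N(0, sigma_study^2),  u_record[i] ~ N(0, sigma_record^2),
u_group[g] ~ N(0, sigma_group^2)
```

`X` holds treatment-coded categorical moderators (ocean basin, hook shape,
optionally their interaction and hook type), `f` is a penalized-spline
smooth of a continuous gear covariate (hooks between floats), and `C` is
the Brownian-motion phylogenetic correlation matrix: for tips `i, j` of a
rooted tree with branch lengths,

```
C[i, j] = (root-to-MRCA shared path length) / sqrt(depth_i * depth_j)
```

which reduces to shared/total depth on an ultrametric tree and stays a
valid correlation matrix on non-ultrametric trees. A jitter of 1e-8 is
added to the diagonal before Cholesky factorization.

The exact binomial likelihood (rather than a Normal approximation of logit
proportions) keeps records with zero or complete mortality without
continuity corrections; those corrections appear only in the screening and
funnel-diagnostic stages, which operate on approximate logit effects.

### Phylogenetic signal

The signal statistic is the posterior proportion of summed group-level
variance attributable to the phylogenetic component,

```
lambda = sigma_phylo^2 / (sigma_phylo^2 + sigma_study^2 + sigma_record^2 + sigma_group^2),
```

computed draw-by-draw, so its posterior respects the joint dependence of
the variance components. There is no additional iid species effect beside
the phylogenetic one; the four variances above are the model's complete
group-level structure.

### Priors

All priors are weakly informative on the logit scale: intercept
Student-t(3, 0, 2.5); fixed-effect coefficients Normal(0, 2); all group and
spline standard deviations half-Student-t(3, 0, 2.5). An alternative
intercept prior (`flat_response`) puts a uniform prior on the response-scale
probability — this makes intercept-only models exactly Beta-conjugate and
is used for oracle cross-checks, not for analysis.

### Splines

The smooth uses a cubic B-spline basis (default 10 functions, equally
spaced interior knots — robust for discrete covariates such as integer hook
counts) with a second-difference penalty, re-expressed in mixed-model form:
the penalty null space contributes a linear fixed-effect column, the range
space contributes random-effect columns scaled by `1/sqrt(eigenvalue)`
whose common standard deviation is sampled like any other variance
component. Covariates with fewer than five distinct values degrade to a
linear term.

## Sampling

The posterior is sampled with an in-package No-U-Turn sampler: analytic
gradients of the joint log posterior on a non-centered parameterization
(species effects enter as `sigma * L z` with `L` the Cholesky factor of
`C`), multiplicative-slice dynamic trajectories with divergence detection
at a 1000-unit drop in the joint density, dual-averaging step-size
adaptation toward a 0.95 target acceptance statistic (0.9 in the reduced
profile) and windowed diagonal mass-matrix estimation during warmup.
Chains are deterministic given the model seed; per-chain seeds derive from
a `SeedSequence` spawn of the sampler seed.

Two profiles ship with the pipeline: `paper` (4 chains, 10,000 post-warmup
draws each after 2,000 warmup) and `ci` (2 chains, 400 post-warmup after
400 warmup, target acceptance 0.9), the latter sized so a ~460-record
clade fit completes in about a minute on one CPU. All reported test and
acceptance quantities use the reduced profile; Monte-Carlo noise is
correspondingly larger but immaterial at the tolerances asserted.

Convergence is summarized per parameter with rank-normalized split-Rhat
and bulk/tail effective sample sizes (via ArviZ, cross-checked in the test
suite against an independently coded textbook implementation); any Rhat at
or above 1.01 sets a warning flag on the fit rather than failing it. Model
comparison uses PSIS-LOO expected log predictive density and Bayesian
stacking weights; posterior predictive checks compare observed record-level
proportions and per-species death totals against replicated datasets.

## Derived quantities

- **HDI**: the narrowest contiguous window containing `ceil(0.95 n)` sorted
  draws; ties resolved toward the lower window. (ArviZ's convention covers
  one more order statistic; the two agree to within one draw.)
- **Probability of direction**: `max(P(d > 0), P(d < 0))` with exact zeros
  split evenly.
- **Pooled AVM**: per draw, the inverse-logit population-level prediction
  averaged over the observed moderator configurations with weights
  proportional to record sample size (group effects at zero); equal
  weighting is available.
- **Species rates**: population terms plus each species' phylogenetic
  effect, back-transformed per draw.
- **Marginal means and ratio contrasts**: the moderator of interest is
  forced to each level across the observed reference grid; ratios are
  formed draw-by-draw, so their HDIs are genuine posterior intervals.
- **Sparse species**: species with fewer than 5 records (configurable) are
  summarized by the Bayes-Laplace estimator — posterior Beta(x+1, n-x+1),
  mean `(x+1)/(n+2)` — with the HDI found by 1-D optimization over the
  interval's lower endpoint (boundary-attached when the density is
  monotone); a Monte-Carlo path is retained as a cross-check.

## Moderator screening and imputation

Screening regresses continuity-corrected logit proportions
(`p~ = (x+0.5)/(n+1)`, delta-method variance `1/(x+0.5) + 1/(n-x+0.5)`)
on candidate moderators with random forests, weighting records by
`1/(v_i + tau2)` with a DerSimonian-Laird between-study variance. Each of
`n_boot` (default 100) replicates resamples whole studies with
replacement; permutation importance is scored on the studies left out of
the replicate — in-sample scoring systematically inflates continuous or
high-cardinality noise predictors. Importances are rescaled so the top
predictor reads 100%, and the informative set is everything above 10% of
the maximum. Taxonomic predictors (genus/family/order) may rank highly but
are excluded from the fixed effects: the phylogenetic correlation matrix
represents that structure in the Bayesian stage. Forest settings: 500
trees, sqrt(p) features per split, minimum node size 5.

Missing moderators are imputed by chained random forests: columns in
increasing-missingness order, each regressed on the other moderators (and
the study identifier — gear configuration clusters within fisheries), with
predictive mean matching (default 5 donors) so numeric imputations are
always observed values; categorical gaps take the forest vote. Iteration
stops when mean out-of-bag error stops improving (default cap 10 sweeps).
Observed cells are never altered; a boolean mask of imputed cells and the
out-of-bag trace are returned. A single completed dataset is produced (no
multiple-imputation pooling).

## Publication-bias diagnostics

The funnel stage uses the same continuity-corrected logit effects, a
DerSimonian-Laird random-effects pooled value, and an Egger-type weighted
regression of effect on standard error with study-cluster-robust
covariance; contours mark two-sided p = 0.10/0.05/0.01 bands that widen
linearly with standard error and meet at the reference at SE zero. This is
a deliberate approximation: a full multivariate REML fit with the
phylogenetic random-effect structure is out of scope, and the diagnostic is
qualitative — the approximation preserves the funnel geometry and the
asymmetry inference. Note that for binomial logit effects the estimate and
its standard error are mechanically correlated at small catch sizes, which
inflates asymmetry rejection rates; calibration holds at moderate catch
sizes (the synthetic scenarios use mean catches of ~25).

## Synthetic data

The generator mirrors the model's data-generating process so every stage is
testable with known truth: a Yule (pure-birth, unit-depth) or star species
tree; species effects drawn MVN(0, sigma_phylo^2 C); iid study, record and
research-group effects; categorical moderators with configurable level
probabilities; a sinusoidal smooth (amplitude 0.3 on the logit scale by
default) over hooks-between-floats; negative-binomial catch sizes (mean
30); binomial deaths; and MCAR masking of hooks-between-floats (4%) and
soak duration (14%). The default scenario is sized like a single-clade
analysis: 13 species, 35 studies of 8–18 records (~460 effect sizes), two
ocean basins with a +1.0 logit ocean contrast, sigma_phylo 0.8, sigma_study
0.5, sigma_record and sigma_research_group 0.3.

Gear covariates are drawn around study-level centers (hook counts
Normal(center, 2.5) rounded and clipped to 15–35; soak durations lognormal
with study-specific location): gear configuration is a property of a
fishery, and this within-study clustering is what makes imputation
learnable, as in the compiled literature data.

What the generator does **not** emulate: taxonomic correlation of the
categorical traits with the tree (body form and ventilation mode are
assigned by species index, not by clade), reporting heterogeneity between
research groups beyond an additive random effect, non-random missingness,
and any dependence of catch size on the moderators. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of them.

A separate single-species generator supports funnel calibration: true logit
rates Normal(theta, tau^2) with overdispersed catch sizes; its suppression
mode censors below-average effects among small-catch records — the
small-study suppression pattern contour-enhanced funnel plots are designed
to reveal.

## Recovery behaviour and known limitations

With 13 species, the likelihood carries limited information about
`sigma_phylo`: the realized species effects are a single correlated draw,
and an oracle given those effects exactly still produces wide intervals
that can exclude the generating value for unlucky draws. Observed coverage
of central 95% intervals across replicate simulations is ~90% for
`sigma_phylo` (at its information-theoretic limit) and at the nominal level
for the ocean contrast and study SD. Coverage checks use central
(equal-tailed) credible intervals; reported uncertainty elsewhere is the
HDI, which for right-skewed SD posteriors sits left of the quantile
interval.

Other limitations: the sampler is single-threaded and chains run serially;
the phylogenetic model uses one fixed tree per fit (sensitivity to tree
choice is exercised by re-running with a different tree index, not by
model averaging); the funnel stage's cluster-robust approximation replaces
the full phylogenetic multivariate fit; and "unknown" moderator levels are
modelled as ordinary category levels rather than being dropped or imputed.
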