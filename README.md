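# elasmoavm

Phylogenetically adjusted Bayesian meta-analysis of elasmobranch
**at-vessel mortality** (AVM) — the proportion of sharks and rays already
dead when pelagic longline gear is retrieved, before any crew handling.
AVM is a key component of fishing mortality for bycatch species: species
with high AVM need measures that reduce catch itself, while species that
mostly come up alive benefit from handling-and-release practices and
retention bans. The package is aimed at fisheries scientists and
quantitative ecologists synthesizing study-level haulback-condition records
across species, fleets and ocean basins.

## The model

Each effect size is one study's record of `x` deaths out of `n` caught for
one species, with gear/operational moderators. The core estimator is a
binomial-Normal hierarchical meta-regression with phylogenetically
correlated species effects:

```
x_i ~ Binomial(n_i, p_i)
logit(p_i) = b0 + X_i'beta + f(z_i) + u_phylo[sp(i)] + u_study[st(i)] + u_rec[i] + u_rg[rg(i)]
u_phylo ~ MVN(0, sigma_phylo^2 C),   other u's iid Normal
```

where `C` is the Brownian-motion correlation matrix derived from a rooted
phylogeny (`C[i,j]` = shared root-to-MRCA path length normalized by tip
depths) and `f` a penalized-spline smooth (e.g. of hooks-between-floats).
Posterior sampling is by an in-package NUTS implementation with analytic
gradients; summaries use posterior means with 95% highest-density
intervals (HDI) and the probability-of-direction statistic. The
phylogenetic signal is reported as
`lambda = sigma_phylo^2 / (sum of all group-level variances)`.

Around the core model the package provides the full workflow:

- `data` — effect-size CSV loading/validation, clade and ocean subsetting;
- `phylo` — Newick/NEXUS parsing, pruning, Brownian correlation matrices;
- `screening` — random-effects-weighted random-forest moderator screening
  (clustered bootstrap, permutation importance) and chained-random-forest
  imputation with predictive mean matching;
- `model` / `inference` — fitting, convergence diagnostics (rank-normalized
  Rhat, bulk/tail ESS), PSIS-LOO comparison with stacking weights,
  posterior predictive checks, pooled/species/marginal-mean/risk-ratio
  summaries, forest plots;
- `sparse` — Bayes-Laplace Beta(x+1, n-x+1) estimation for data-poor
  species, including zero observed deaths;
- `pubbias` — contour-enhanced funnel plots and a cluster-robust
  Egger-type asymmetry test;
- `synthetic` — generators with known ground truth for every stage;
- `cli` — `elasmoavm simulate|screen|impute|fit|summarize|funnel|run-all`.

Key estimators follow scikit-learn conventions
(`BinomialPhyloMetaRegression`, `ModeratorScreener`, `ChainedForestImputer`,
`BayesLaplaceEstimator` with `fit`/`transform` and trailing-underscore
fitted attributes); module-level functions wrap them for dataset-level use.

## Worked example

```python
from elasmoavm import (simulate_dataset, TruthConfig, brownian_correlation,
                       canonical_spec, SamplerSettings, fit_model, pooled_avm,
                       phylo_signal, ratio_contrast, bayes_laplace_estimate)
from elasmoavm.phylo import parse_tree_string

ds, truth = simulate_dataset(
    TruthConfig(n_species=8, n_studies=20, records_per_study=(5, 9),
                miss_hooks_between_floats=0.0, miss_soak_duration=0.0),
    seed=1)
tree = parse_tree_string(truth.tree_newick)
corr = brownian_correlation(tree, sorted(ds.frame["species"].unique()))
spec = canonical_spec(corr, fixed_effects=["ocean"],
                      sampler=SamplerSettings(chains=2, draws=400, warmup=400,
                                              seed=5, target_accept=0.9))
fit = fit_model(ds, spec)
p = pooled_avm(fit)
print(f"pooled AVM: {p.mean:.3f} (95% HDI {p.hdi_low:.3f}-{p.hdi_high:.3f})")
```

Output of the full example script (reduced sampler profile):

```
records: 140 | species: 8
pooled AVM: 0.568 (95% HDI 0.436-0.696)
phylogenetic signal: 0.07 (95% HDI 0.00-0.28)  [truth 0.60]
Pacific/Atlantic risk ratio: 1.52 (95% HDI 1.28-1.75), P(ratio>1) = 1.000
sparse species, 0 dead of 18: mean 0.050 (95% HDI 0.000-0.146)
max Rhat: 1.0083
```

Reading the numbers: the pooled AVM is the sample-size-weighted posterior
mean mortality at the population level (group effects at zero). The
generator injected a +1.0 logit ocean contrast, which the risk ratio
recovers as Pacific records being ~1.5x as likely to be dead at haulback,
with probability ~1 that the ratio exceeds 1. The signal estimate
illustrates how little information 8 species carry about the phylogenetic
variance share — its posterior is wide and shrinks toward small values at
this scale (the truth, 0.60, is recovered at nominal rates only across
replicates at larger scales; see `docs/methods.md`). The sparse-species
line shows the Bayes-Laplace estimate for a species with zero observed
deaths: `(0+1)/(18+2) = 0.05` rather than an implausible exact zero.

The same pipeline runs end-to-end from a shell:

```
elasmoavm run-all --seed 11 --profile ci --outdir out/
```

writing `report.json`, summary tables (CSV), diagnostic and funnel plots,
and a manifest with the config hash and per-stage seeds.

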