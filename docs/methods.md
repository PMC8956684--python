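# Methods

## Statistical model

Data are a cohort of n samples with p continuous features
X ∈ ℝ^{n×p} and binary labels y ∈ {0, 1}^n. All models are logistic
regressions on standardized features: for a feature subset S,

P(y = 1 | x) = expit(β₀ + Σ_{j∈S} β_j (x_j − μ_j) / σ_j),

where μ_j, σ_j are training-fold means and standard deviations.
Model quality is the cross-validated *classification error*: the mean
over held-out folds of the misclassification proportion at the 0.5
probability cutoff. Folds are stratified by class and the k-fold scheme
is repeated with reshuffling.

## Sparse wrapper search

1. **Screening (dimension 1).** Every one-feature model is scored by
   repeated stratified k-fold CV error. The retention threshold is the
   empirical α-quantile of those errors; models with error ≤ threshold
   are retained, and their features form the *screened* set. Only
   screened features can appear in larger models.
2. **Growth (dimension d ≥ 2).** Each retained (d−1)-model is extended
   by one screened feature not already in it. When the number of
   achievable extensions is at most `m_models` (or `m_models=None`),
   candidates are enumerated exhaustively; otherwise `m_models`
   candidates are sampled uniformly with replacement and deduplicated.
   Candidates are scored by the same CV error and again filtered at the
   per-dimension empirical α-quantile. Growth stops at `p_max` or when
   no new candidate exists.
3. The result is a `ModelSet`: retained models per dimension, with
   errors, thresholds and the screened feature list.

### Defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| `alpha` | 0.05 | retain only the best 5% per dimension; the per-dimension quantile adapts the bar to each dimension's error distribution |
| `p_max` | 5 | small panels keep events-per-variable high on cohort-scale data (44 events / 5 variables ≈ 8.8) |
| `k_folds`, `n_repeats` | 10, 10 | repeated 10-fold CV stabilizes small-sample error estimates |
| `m_models` | 100 | caps per-dimension work; below the exhaustive count it becomes a randomized beam |
| cutoff | 0.5 | classification error is defined at the natural probability cutoff |
| `min_occurrence` | 0.10 | a sign reversal is only called antagonistic if the feature appears in ≥10% of retained models |

## Single and associative effects

The *single* effect of feature j is the slope of the one-feature
logistic fit (a marginal analysis). The *associative* effect is the
collection of j's slopes across all retained multivariate models
containing j (conditional analyses), summarized by median and range.
Classification:

- **oncogenic**: single > 0 and median associative > 0;
- **protective**: both < 0;
- **antagonistic**: signs disagree and occurrence ≥ `min_occurrence`;
- **unstable**: discordant but below the occurrence filter, or an
  exact-zero coefficient (no sign).

The single effect is deliberately the marginal fit even when the
feature also appears in a retained one-feature model: antagonism is
defined as marginal-versus-conditional sign reversal, so the
associative summary is taken over *multivariate* models when any exist.
Note that marginal logistic slopes are attenuated whenever another
informative covariate is omitted, even with independent covariates
(non-collapsibility of the odds ratio); sign *reversal*, as opposed to
attenuation, requires correlation structure.

Synonym detection (`find_synonyms`) lists feature pairs that are
swap-equivalent: two retained models of the same dimension differing in
exactly one position with (near-)equal test metric — the substitution
axis of the model library.

## Networks

`build_network` maps a model set to an undirected graph: nodes are all
features appearing in at least one retained model, node `size` is the
percentage of retained models containing the feature, node `sign` the
sign of the median associative coefficient, edge `weight` the
percentage of models containing both endpoints, with bootstrap Spearman
correlation (`rho`, `rho_sign`) as edge attributes.
`focal_subnetwork` restricts to models containing a focal feature,
recomputes percentages relative to that restricted set, and signs nodes
by their *single* effect.

Spearman correlation uses average ranks for ties; constant vectors are
a flagged error. `bootstrap_correlation` draws `n_boot` (default 5000)
paired resamples, reports the percentile 95% interval and a two-sided
bootstrap p-value floored at 2/`n_boot` (standard resampling practice;
a resampled p of exactly zero is an artifact of finite resampling).

## Evaluation

Retained models are refit on the full training split, frozen
(intercept, slopes, training standardization) and applied to the
held-out split: confusion metrics (cutoff 0.5, undefined ratios
reported as NaN and named), ROC curves by threshold sweep, trapezoidal
AUC, and the ROC *region* — the pointwise min/max envelope of all
retained models' interpolated ROC curves, conveying the spread of the
library rather than a single curve. EPV (events per variable) is the
smaller outcome-category count divided by model dimension. The lasso
baseline fits an L1-penalized logistic regression (liblinear), picking
the penalty from 30 log-spaced values by stratified 10-fold CV
misclassification — mirroring the wrapper's criterion — and reports
test metrics with bootstrap percentile intervals.

## Synthetic cohorts

`generate_cohort` draws features from a standard Gaussian with
equicorrelated blocks (block (idx, ρ) is positive definite iff
ρ > −1/(m−1) for block size m), plants conditional log-odds slopes on
chosen features, and solves the intercept by root-finding so that
E[P(y=1)] matches the requested prevalence (the linear predictor is
N(β₀, β'Rβ) under the block correlation R). Labels are Bernoulli
draws, so realized prevalence fluctuates. `simpson_config` places a
focal feature (small positive conditional effect) with a strong
positively-acting confounder at negative correlation and validates
analytically that the focal *marginal* slope has the opposite sign
(β_focal · (β_focal + β_conf·ρ) < 0).

Scope and limits: features are Gaussian and homoscedastic — no heavy
tails, batch effects or missingness; labels follow a correctly
specified logistic model; correlation blocks are equicorrelated. The
generator is a test harness for the algorithms, not a simulator of any
particular assay.

## Numerical choices

- **Logistic fitting** is a damped Newton iteration with step halving,
  an unpenalized intercept and a tiny ridge (1e-6) on slopes only, so
  separated data yield large-but-finite slopes instead of divergence;
  fits with |slope| > 10 are flagged `separated`. Coefficients agree
  with unpenalized maximum likelihood to ~1e-6 on non-separated data.
- **Shared CV folds.** All models scored within one search share one
  fold set drawn from the run seed. This makes errors comparable across
  models (same partitions), the search deterministic, and brute-force
  oracle comparisons exact.
- **Retention threshold** uses the empirical quantile with
  `method="higher"`, so the threshold is always an observed error:
  retention is tie-inclusive and α → 1 retains everything.
- **Oracle-equivalence regime.** Greedy growth only sees extensions of
  retained (d−1)-models, so for small α a dimension-d combination can
  become unreachable when all of its (d−1)-subsets were dropped, and
  the greedy α-quantile then differs from the brute-force one by an
  order statistic. At α = 0.9 on 8 features at most two pairs are
  dropped at dimension 2, so no triple can lose all its parents and
  greedy-equals-brute-force holds structurally; the acceptance suite
  tests exactly that regime rather than widening tolerances.
- **Determinism.** One global seed deterministically derives per-stage
  seeds (split, search, lasso, network bootstrap) via an FNV-style
  hash, so a pipeline rerun reproduces every artifact byte for byte.

## Limitations

- CV error at the 0.5 cutoff is a coarse criterion on imbalanced data;
  prevalence far from 0.5 will bias retention toward majority-class
  models.
- The randomized beam (`m_models` below the exhaustive count) trades
  completeness for speed; results then depend on the seed, though
  reproducibly so.
- Associative medians over few models are noisy; the occurrence filter
  controls, but does not eliminate, spurious antagonism calls.
- Bootstrap percentile intervals undercover slightly at small n; the
  acceptance suite checks coverage ≈95% at n = 60.
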