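# swagnet

Sparse wrapper model sets for binary classification on expression-style
data, with single-versus-associative effect analysis and model
co-occurrence networks.

## The problem

Biomarker panel selection from a continuous feature matrix (for example
log-intensity expression values) with a binary outcome usually produces
a *single* "best" model, discarding the fact that many small feature
combinations are nearly equally predictive. This package implements a
sparse wrapper strategy that instead retains a whole *library* of
strong low-dimensional logistic models and then analyzes the library as
an object in its own right:

- **Screening and growth.** Every one-feature logistic model is scored
  by repeated stratified k-fold cross-validated misclassification.
  Features in the best α-fraction survive; retained models of dimension
  d − 1 are extended by one screened feature at a time, and each
  dimension again keeps only the best α-fraction, up to a dimension cap.
- **Single vs associative effects.** Each screened feature gets a
  *single* coefficient (its marginal one-feature logistic slope on the
  standardized design) and an *associative* coefficient distribution
  (its slope in every retained multivariate model that contains it,
  summarized by median and range). A feature whose single and median
  associative signs disagree — while appearing in at least 10% of
  retained models — is flagged **antagonistic**: a Yule–Simpson-style
  sign reversal between marginal and conditional analyses. Concordant
  features are classed oncogenic (both positive) or protective (both
  negative).
- **Networks.** The model library induces a co-occurrence graph: node
  size is a feature's occurrence rate across retained models, edge
  thickness the rate at which two features appear in the same model,
  with bootstrap Spearman correlations as edge attributes.
- **Evaluation.** Retained models are refit on training data, frozen
  (coefficients plus standardization), and scored on a held-out split:
  confusion metrics, ROC curves, the ROC *region* spanned by the whole
  library, events-per-variable, and an L1-penalized (lasso) logistic
  baseline with bootstrap confidence intervals for comparison.

A synthetic-cohort generator (correlated Gaussian blocks, planted
conditional effects, adjustable prevalence) supports testing; its
`simpson_config` helper builds cohorts with a guaranteed marginal sign
flip for the focal feature.

## Worked example

```python
from swagnet import CohortConfig, generate_cohort, SparseWrapperSearch
from swagnet.cohort import SplitSpec, split_cohort

cohort = generate_cohort(CohortConfig(
    n_samples=250, n_features=15, prevalence=0.45,
    effects={0: 2.0, 1: -2.0},              # conditional log-odds slopes
    correlation_blocks=[((0, 2), 0.5)],     # features 0 and 2 correlate
    seed=7))
train, test = split_cohort(cohort, SplitSpec(test_fraction=0.2, seed=0))

results = SparseWrapperSearch(train, p_max=3, alpha=0.2, m_models=60,
                              k_folds=10, n_repeats=2, seed=1).fit()
print(results.summary())
```

```
Sparse wrapper search results
================================================================
training samples: 200 (90 cases / 110 controls)
features screened: 15 -> 5 retained (alpha = 0.2, threshold = 0.4500)
cv: 10-fold x 2 repeats, seed 1

 dim  models  min err   median  max err  threshold
   1       5   0.2675   0.3850   0.4500     0.4500
   2       3   0.1950   0.2700   0.2800     0.2800
   3       3   0.1950   0.1950   0.1950     0.1950

total retained models: 11 over 5 distinct features
```

```python
print(results.effect_profiles().to_string(index=False))
```

```
feature  beta_single  median_associative  assoc_min  assoc_max  occurrence_pct effect_class
feat-01     1.557295            2.070177   1.557295   2.082531       63.636364    oncogenic
feat-02    -0.960319           -1.481953  -1.483955  -0.960319       45.454545   protective
feat-09    -0.010640           -0.010640  -0.015248   0.074260       27.272727   protective
feat-15     0.024561            0.024561  -0.011581   0.158764       27.272727    oncogenic
feat-03     0.642941            0.312096  -0.018749   0.642941       18.181818    oncogenic
```

Both planted features are recovered with the right signs; held-out
evaluation ranks their joint models first:

```python
ev = results.evaluate(test)
print(ev["table"][["features", "dimension", "test_error", "auc"]]
      .sort_values("auc", ascending=False).head(4).to_string(index=False))
```

```
               features  dimension  test_error      auc
feat-01|feat-02|feat-09          3        0.22 0.892110
feat-01|feat-02|feat-15          3        0.22 0.892110
        feat-01|feat-02          2        0.22 0.892110
feat-01|feat-02|feat-03          3        0.22 0.892110
```

`results.network()` returns the co-occurrence graph (networkx), and
`results.frozen_models()` the serializable fitted models for external
validation via `apply_frozen_models`.

## Command line

Each pipeline stage is a subcommand of `swagnet`; `run` executes the
whole analysis from a YAML config and writes a reproducible artifact
bundle (model set, per-model metrics, frozen models, effect table,
networks in GraphML/TSV, lasso baseline, manifest):

```
swagnet simulate --config sim.yaml --matrix m.tsv --labels l.tsv
swagnet run --config run.yaml
swagnet swag --matrix m.tsv --labels l.tsv --out models.json
swagnet effects --matrix m.tsv --labels l.tsv --model-set models.json --out effects.tsv
swagnet network --matrix m.tsv --labels l.tsv --model-set models.json --graphml net.graphml
swagnet validate --frozen frozen_models.json --matrix m2.tsv --labels l2.tsv --out-dir val/
```

Exit codes: 0 success, 2 configuration error, 3 data error. A rerun of
`swagnet run` with the same config reproduces every artifact byte for
byte (one global seed deterministically derives per-stage seeds).

## Reproduction

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
writes the headline quantities (EPV arithmetic, stratified split
structure, a full pipeline run, conditional-effect recovery, antagonism
detection and false-positive rates, greedy-versus-brute-force agreement,
rank-correlation checks) as JSON. The test suite covers the same ground
plus unit and property-based tests: `python -m pytest -q tests/`.

See `docs/methods.md` for the statistical model, parameter defaults and
numerical choices.
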