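# sccanet

Sparse canonical correlation analysis linking functional connectomes to
psychiatric symptom dimensions.

## What problem this solves

Psychiatric symptoms cross diagnostic boundaries, and so do the brain
network abnormalities behind them. Given per-subject functional
connectivity matrices (node × node edge weights), item-level symptom
ratings and demographic/motion covariates, `sccanet` finds *linked
dimensions*: sparse patterns of connectivity and sparse sets of symptom
items whose subject scores are maximally correlated. It is written for
researchers in network neuroscience and multivariate biostatistics who
want the full inferential pipeline — not just the decomposition — as a
tested, scriptable library.

The core is sparse CCA via penalized matrix decomposition. For
standardized views `X` (n × p edges) and `Y` (n × q items), each canonical
variate solves

    maximize u' X'Y v   s.t.  ||u||2^2 <= 1, ||v||2^2 <= 1,
                              ||u||1 <= c1,  ||v||1 <= c2

by alternating soft-thresholded updates, with rank-1 deflation for further
variates. Around that core the package provides:

* feature engineering: edge vectorization (264 nodes → 34,980 features),
  median-absolute-deviation feature selection, covariate residualization,
  standardization;
* sparsity tuning by resampled grid search and scree-based variate
  selection;
* permutation significance with clinical-loading variate matching and
  Benjamini–Hochberg FDR;
* stability selection of individual edges (99% CI) and items (95% CI) by
  two-thirds + replaced-third resampling;
* community-level loading summaries with size-preserving label-permutation
  tests, cross-dimension common-edge overlap against a density-matched
  null, and nodal loading strength;
* developmental models `score ~ Sex + s(Age)` with penalized splines and
  age × sex interaction tests;
* a synthetic-cohort generator with planted ground truth, plain-CSV
  interchange formats, and an end-to-end pipeline driver with
  discovery/replication roles.

## A worked example

```python
from sccanet.features import (filter_by_mad, residualize, standardize,
                              vectorize_connectivity)
from sccanet.scca import SccaParams, fit_scca
from sccanet.synthetic import CohortConfig, generate_cohort, score_recovery

cohort = generate_cohort(CohortConfig(
    n_subjects=500, n_nodes=25, n_items=40, n_latent=2,
    effect_scales=(3.0, 2.0), noise_sd=1.0, seed=7))

fm = filter_by_mad(vectorize_connectivity(cohort.connectivity, cohort.subjects), 1.0)
X = standardize(residualize(fm.values, cohort.covariates))
Y = standardize(residualize(cohort.clinical.to_numpy(float),
                            cohort.covariates, ("age", "sex", "race")))
model = fit_scca(X, Y, SccaParams(c1_frac=0.3, c2_frac=0.5, n_components=2))
print(score_recovery(cohort.truth, model, fm.feature_index).round(3))
```

prints (`examples/01_simulate_and_recover.py`):

```
features entering sCCA: 300
canonical correlations: [0.875 0.768]
 true_dim  matched_component  u_recovery  v_recovery  recovery
        0                  0       0.985       0.972     0.978
        1                  1       0.970       0.966     0.968
```

Two latent dimensions were planted linking sparse sets of edges to sparse
sets of items; the fitted variates' subject scores correlate at 0.88 and
0.77 across views, and the estimated loading vectors correlate with the
planted ones at ≈ 0.97 after sign/order alignment — the model found what
was put in. The `examples/` directory walks through every capability the
same way (tuning, permutation and stability inference, module summaries,
age/sex effects, the file-based pipeline).

From a shell:

```bash
sccanet simulate cohort_dir --n-subjects 250
sccanet run config.yaml   # paths, penalties, B/R, seed, role in YAML
```

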