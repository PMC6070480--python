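"""Developmental effects on dimension scores: score ~ Sex + s(Age).

Refits the sparse CCA on data residualized for race and motion only (age
and sex must stay in), matches the variates back to the reference, and
models each dimension's connectivity score with a penalized-spline GAM.
"""

from sccanet.devsex import dimension_scores, fit_age_sex_gam
from sccanet.features import filter_by_mad, residualize, standardize, vectorize_connectivity
from sccanet.scca import SccaParams, fit_scca
from sccanet.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(
    CohortConfig(
        n_subjects=400, n_nodes=20, n_items=30, n_latent=2,
        # strong age/sex confound effects so the developmental model has signal
        confound_effects={"age": (0.06, 0.02), "sex": (0.3, 0.1),
                          "race": (0.05, 0.05), "motion": (0.3, 0.0)},
        seed=13,
    )
)
fm = filter_by_mad(vectorize_connectivity(cohort.connectivity, cohort.subjects), 1.0)
cov = cohort.covariates
clinical = cohort.clinical.to_numpy(dtype=float)

# reference fit: all confounds removed
X = standardize(residualize(fm.values, cov))
Y = standardize(residualize(clinical, cov, ("age", "sex", "race")))
params = SccaParams(c1_frac=0.4, c2_frac=0.6, n_components=2)
reference = fit_scca(X, Y, params)

# developmental fit: keep age and sex in the data
X_partial = standardize(residualize(fm.values, cov, ("race", "motion")))
Y_partial = standardize(residualize(clinical, cov, ("race",)))
scores = dimension_scores(X_partial, Y_partial, reference, params, selected=[0, 1])

result = fit_age_sex_gam(scores, cov["age"].to_numpy(), cov["sex"].to_numpy(),
                         interaction=True)
print(result.table.round(4).to_string(index=False))
print("age_edf near 1 means the age trend is linear; sex_coef is the shift "
      "between sexes; q-values are FDR-adjusted across dimensions per family.")
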