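"""Simulate a cohort with planted canonical structure and recover it.

Generates 500 subjects with two latent dimensions linking connectivity
edges to symptom items, runs the standard feature pipeline, fits a
two-component sparse CCA and reports how well the planted loadings were
recovered (1.0 = perfect, ~0 = nothing).
"""

import numpy as np

from sccanet.features import filter_by_mad, residualize, standardize, vectorize_connectivity
from sccanet.scca import SccaParams, fit_scca
from sccanet.synthetic import CohortConfig, generate_cohort, score_recovery

cohort = generate_cohort(
    CohortConfig(n_subjects=500, n_nodes=25, n_items=40, n_latent=2,
                 effect_scales=(3.0, 2.0), noise_sd=1.0, seed=7)
)

fm = vectorize_connectivity(cohort.connectivity, cohort.subjects)
fm = filter_by_mad(fm, 1.0)  # drops the 25 constant diagonal features
X = standardize(residualize(fm.values, cohort.covariates))
Y = standardize(
    residualize(cohort.clinical.to_numpy(dtype=float), cohort.covariates, ("age", "sex", "race"))
)

model = fit_scca(X, Y, SccaParams(c1_frac=0.3, c2_frac=0.5, n_components=2))
report = score_recovery(cohort.truth, model, fm.feature_index)

print(f"features entering sCCA: {fm.n_features}")
print(f"canonical correlations: {np.round(model.correlations, 3)}")
print(report.round(3).to_string(index=False))
print("recovery is the sign/order-aligned |correlation| between estimated "
      "and planted loadings; values near 1 mean the dimension was found.")
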