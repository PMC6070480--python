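"""Summarize a variate's edge loadings on the community structure.

Places stability-surviving edge loadings back on the node grid, averages
them within and between communities, and tests each community-pair cell
against a size-preserving label-permutation null.  Also shows the
cross-dimension common-edge overlap and nodal strengths.
"""

import numpy as np

from sccanet.features import filter_by_mad, residualize, standardize, vectorize_connectivity
from sccanet.inference import stability_resample
from sccanet.netmods import (
    CommunityAssignment,
    build_loading_matrix,
    common_edge_overlap,
    module_label_permutation,
    nodal_strength,
)
from sccanet.scca import SccaParams, fit_scca
from sccanet.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(
    CohortConfig(n_subjects=300, n_nodes=20, n_items=30, n_latent=2, seed=5)
)
comm = CommunityAssignment(cohort.communities)
fm = filter_by_mad(vectorize_connectivity(cohort.connectivity, cohort.subjects), 1.0)
X = standardize(residualize(fm.values, cohort.covariates))
Y = standardize(
    residualize(cohort.clinical.to_numpy(dtype=float), cohort.covariates, ("age", "sex", "race"))
)

params = SccaParams(c1_frac=0.4, c2_frac=0.6, n_components=2)
model = fit_scca(X, Y, params)
stab = stability_resample(X, Y, params, model, selected=[0, 1], R=100, seed=0)

W = [
    build_loading_matrix(model.U[:, k], fm.feature_index, comm.n_nodes,
                         significant_mask=stab.u_significant[:, k])
    for k in (0, 1)
]
result = module_label_permutation(W[0], comm, B=500, seed=1)
print("community x community mean loadings (variate 0):")
print(result.mean_loading.round(3).to_string())
print("FDR q-values (label permutation, B=500):")
print(result.q.round(3).to_string())

overlap = common_edge_overlap([w != 0 for w in W], W, B=500, seed=2)
strengths = nodal_strength(overlap.mean_abs_loading)
print(f"edges common to both variates surviving the null: "
      f"{int(np.sum(np.triu(overlap.common_edge_mask, 1)))} "
      f"({overlap.n_eliminated} eliminated by the null)")
print(f"top-3 nodes by loading strength: {np.argsort(-strengths)[:3] + 1}")
print("cells with small q carry more loading than size-matched random "
      "communities.  The simulator plants disjoint edge supports per "
      "dimension, so an empty common-edge set is the expected outcome here; "
      "overlapping supports in real data would survive the null.")
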