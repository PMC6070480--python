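import numpy as np
import pytest

from sccanet.features import filter_by_mad, residualize, standardize, vectorize_connectivity
from sccanet.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200 subjects, 18 nodes, 24 items, two planted dimensions."""
    return generate_cohort(
        CohortConfig(n_subjects=200, n_nodes=18, n_items=24, n_latent=2, seed=42)
    )


def prepare_views(cohort, mad_fraction=1.0):
    """Standard feature pipeline: vectorize -> MAD filter -> residualize -> standardize."""
    fm = vectorize_connectivity(cohort.connectivity, cohort.subjects)
    fm = filter_by_mad(fm, mad_fraction)
    X = standardize(residualize(fm.values, cohort.covariates))
    Y = standardize(
        residualize(cohort.clinical.to_numpy(dtype=float), cohort.covariates, ("age", "sex", "race"))
    )
    return fm, X, Y


@pytest.fixture(scope="session")
def small_views(small_cohort):
    return prepare_views(small_cohort)
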