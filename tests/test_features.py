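import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccanet.features import (
    FeatureMatrix,
    filter_by_mad,
    mad,
    rebuild_matrix,
    residualize,
    standardize,
    vectorize_connectivity,
)


def _random_symmetric_stack(rng, n_subj, n_nodes):
    mats = rng.normal(size=(n_subj, n_nodes, n_nodes))
    mats = (mats + mats.transpose(0, 2, 1)) / 2
    for m in mats:
        np.fill_diagonal(m, 1.0)
    return mats


class TestVectorize:
    def test_feature_count_264_nodes(self):
        """264-node correlation matrices carry 34,980 unique features."""
        rng = np.random.default_rng(0)
        fm = vectorize_connectivity(_random_symmetric_stack(rng, 1, 264))
        assert fm.n_features == 34980

    @pytest.mark.parametrize("n_nodes,expected", [(3, 6), (5, 15), (10, 55)])
    def test_feature_count_small(self, n_nodes, expected):
        rng = np.random.default_rng(1)
        fm = vectorize_connectivity(_random_symmetric_stack(rng, 2, n_nodes))
        assert fm.n_features == expected
        # upper triangle including diagonal, row-major
        assert tuple(fm.feature_index[0]) == (0, 0)
        assert tuple(fm.feature_index[1]) == (0, 1)

    def test_asymmetric_matrix_rejected_naming_subject(self):
        rng = np.random.default_rng(2)
        mats = _random_symmetric_stack(rng, 2, 4)
        mats[1, 1, 2] += 1e-3
        with pytest.raises(ValueError, match="sub-b"):
            vectorize_connectivity(mats, subjects=["sub-a", "sub-b"])

    def test_round_trip_rebuild(self):
        rng = np.random.default_rng(3)
        mats = _random_symmetric_stack(rng, 3, 6)
        fm = vectorize_connectivity(mats)
        rebuilt = rebuild_matrix(fm.values[1], fm.feature_index, 6)
        assert np.array_equal(rebuilt, mats[1])

    def test_duplicate_feature_index_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(
                values=np.zeros((2, 2)),
                feature_index=np.array([[0, 1], [0, 1]]),
                subjects=np.arange(2),
            )


class TestMad:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 100], 1.0),   # median 3, deviations [2,1,0,1,97]
            ([1, 1, 3, 5], 1.0),        # even-length midpoint medians
            ([7, 7, 7], 0.0),
            ([5], 0.0),
        ],
    )
    def test_direct_evaluation(self, values, expected):
        assert mad(np.array(values, dtype=float)) == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mad(np.array([]))


class TestFilterByMad:
    def _fm(self, values):
        values = np.asarray(values, dtype=float)
        p = values.shape[1]
        idx = np.column_stack([np.zeros(p, dtype=int), np.arange(p)])
        return FeatureMatrix(values=values, feature_index=idx,
                             subjects=np.arange(values.shape[0]))

    def test_top_fraction_by_direct_mad(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(30, 20)) * rng.uniform(0.1, 5, size=20)
        fm = self._fm(values)
        kept = filter_by_mad(fm, 0.1)
        assert kept.n_features == 2
        mads = np.array([mad(values[:, j]) for j in range(20)])
        expected = np.sort(np.argsort(-mads)[:2])
        assert np.array_equal(kept.feature_index[:, 1], expected)

    def test_fraction_one_drops_only_zero_mad(self):
        rng = np.random.default_rng(5)
        mats = _random_symmetric_stack(rng, 20, 6)
        fm = vectorize_connectivity(mats)
        kept = filter_by_mad(fm, 1.0)
        # the 6 unit-diagonal features are constant and must go
        assert kept.n_features == 15
        assert np.all(kept.feature_index[:, 0] != kept.feature_index[:, 1])

    def test_diagonal_never_retained(self):
        rng = np.random.default_rng(6)
        mats = _random_symmetric_stack(rng, 20, 8)
        kept = filter_by_mad(vectorize_connectivity(mats), 0.3)
        assert np.all(kept.feature_index[:, 0] != kept.feature_index[:, 1])

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        fm = self._fm(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError):
            filter_by_mad(fm, fraction)

    def test_permutation_equivariance(self):
        """Reordering feature columns reorders, but does not change, the kept set."""
        rng = np.random.default_rng(7)
        values = rng.normal(size=(25, 12)) * rng.uniform(0.5, 3, size=12)
        fm = self._fm(values)
        perm = rng.permutation(12)
        fm_perm = FeatureMatrix(
            values=values[:, perm], feature_index=fm.feature_index[perm],
            subjects=fm.subjects,
        )
        kept = filter_by_mad(fm, 0.5)
        kept_perm = filter_by_mad(fm_perm, 0.5)
        assert set(map(tuple, kept.feature_index)) == set(map(tuple, kept_perm.feature_index))


class TestResidualize:
    def _covariates(self, rng, n):
        return pd.DataFrame(
            {
                "age": rng.uniform(8, 22, n),
                "sex": rng.integers(0, 2, n),
                "race": rng.choice(list("ABC"), n),
                "motion": rng.lognormal(-2, 0.5, n),
            }
        )

    def test_exact_linear_fit_leaves_zero_residual(self):
        rng = np.random.default_rng(8)
        cov = self._covariates(rng, 100)
        col = 3.0 * cov["age"].to_numpy() - 1.0
        res = residualize(col[:, None], cov, ("age",))
        assert np.max(np.abs(res)) < 1e-8 * np.abs(col).max()

    def test_empty_subset_mean_centers(self):
        rng = np.random.default_rng(9)
        cov = self._covariates(rng, 50)
        col = rng.normal(5, 2, size=(50, 3))
        res = residualize(col, cov, ())
        assert np.allclose(res, col - col.mean(axis=0))

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(10)
        cov = self._covariates(rng, 120)
        mat = rng.normal(size=(120, 5))
        res = residualize(mat, cov)
        for name in ("age", "motion"):
            inner = res.T @ cov[name].to_numpy()
            assert np.max(np.abs(inner)) < 1e-8 * np.abs(mat).max() * 120
        assert np.max(np.abs(res.T @ (cov["sex"] == 1).to_numpy(dtype=float))) < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        cov = self._covariates(rng, 80)
        mat = rng.normal(size=(80, 4))
        once = residualize(mat, cov)
        twice = residualize(once, cov)
        assert np.max(np.abs(once - twice)) < 1e-10

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(12)
        cov = self._covariates(rng, 40)
        cov["age2"] = 2 * cov["age"]
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.normal(size=(40, 2)), cov, ("age", "age2"))


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(13)
        out = standardize(rng.normal(3, 7, size=(50, 4)))
        assert np.allclose(out.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.std(axis=0), 1, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(14)
        out = standardize(rng.normal(size=(60, 3)))
        assert np.allclose(standardize(out), out, atol=1e-12)

    def test_two_point_column(self):
        assert np.allclose(standardize(np.array([[0.0], [2.0]])), [[-1.0], [1.0]])

    def test_constant_column_rejected_by_name(self):
        mat = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="1"):
            standardize(mat)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
def test_vectorize_rebuild_round_trip_property(n_nodes, seed):
    """Vectorization and matrix rebuild are exact inverses for any symmetric input."""
    rng = np.random.default_rng(seed)
    mat = rng.normal(size=(n_nodes, n_nodes))
    mat = (mat + mat.T) / 2
    fm = vectorize_connectivity([mat])
    assert np.array_equal(rebuild_matrix(fm.values[0], fm.feature_index, n_nodes), mat)


def test_fisher_z_transform_is_monotone_arctanh():
    rng = np.random.default_rng(15)
    mats = _random_symmetric_stack(rng, 3, 5)
    mats = np.tanh(mats)  # keep edges inside (-1, 1)
    for m in mats:
        np.fill_diagonal(m, 1.0)
    raw = vectorize_connectivity(mats)
    z = vectorize_connectivity(mats, fisher_z=True)
    off = raw.feature_index[:, 0] != raw.feature_index[:, 1]
    assert np.allclose(z.values[:, off], np.arctanh(raw.values[:, off]))
    assert np.isfinite(z.values).all()
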