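import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccanet.scca import (
    SccaParams,
    covariance_explained,
    fit_component,
    fit_scca,
    l1_constrain,
    soft_threshold,
)
from sccanet.synthetic import CohortConfig, generate_cohort, score_recovery

from conftest import prepare_views


def _l1_constrain_grid_oracle(a, c, n_grid=200000):
    """Brute-force reference: scan the soft-threshold path for the smallest delta."""
    a = np.asarray(a, dtype=float)
    for delta in np.linspace(0, np.abs(a).max(), n_grid):
        s = soft_threshold(a, delta)
        norm = np.linalg.norm(s)
        if norm == 0:
            break
        w = s / norm
        if np.sum(np.abs(w)) <= c:
            return w
    idx = int(np.argmax(np.abs(a)))
    w = np.zeros_like(a)
    w[idx] = np.sign(a[idx])
    return w


class TestSoftThreshold:
    def test_definition(self):
        assert np.allclose(soft_threshold(np.array([3.0, -3.0, 0.5]), 1.0), [2.0, -2.0, 0.0])

    def test_zero_delta_is_identity(self):
        a = np.array([1.0, -2.0, 0.0])
        assert np.array_equal(soft_threshold(a, 0.0), a)

    def test_large_delta_annihilates(self):
        assert not np.any(soft_threshold(np.array([1.0, -2.0]), 2.5))


class TestL1Constrain:
    def test_inactive_bound_returns_unit_input(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        w = l1_constrain(a, np.sqrt(40))
        assert np.allclose(w, a / np.linalg.norm(a))

    def test_c_equal_one_selects_argmax_lowest_index(self):
        w = l1_constrain(np.array([2.0, -3.0, 3.0, 1.0]), 1.0)
        assert np.array_equal(w, [0.0, -1.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=30)
        c = float(rng.uniform(1.2, np.sqrt(30) * 0.9))
        w = l1_constrain(a, c)
        oracle = _l1_constrain_grid_oracle(a, c)
        assert np.max(np.abs(w - oracle)) < 1e-3

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_contract_unit_l2_and_l1_cap(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 100))
        a = rng.normal(size=d) * 10.0 ** rng.integers(-2, 3)
        c = float(rng.uniform(1.0, np.sqrt(d)))
        w = l1_constrain(a, c)
        assert abs(np.linalg.norm(w) - 1) < 1e-9
        assert np.sum(np.abs(w)) <= c + 1e-6

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            l1_constrain(np.zeros(4), 1.5)


class TestFitComponent:
    def test_rank_one_recovers_factors(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50); a /= np.linalg.norm(a)
        b = rng.normal(size=12); b /= np.linalg.norm(b)
        u, v, d, _ = fit_component(3.7 * np.outer(a, b), np.sqrt(50), np.sqrt(12))
        assert abs(abs(a @ u)) > 0.9999
        assert abs(abs(b @ v)) > 0.9999
        assert abs(d - 3.7) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_svd_limit(self, seed):
        """Without active L1 constraints the solver is the leading SVD pair."""
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(30, 20))
        u, v, d, _ = fit_component(Z, np.sqrt(30), np.sqrt(20))
        U, S, Vt = np.linalg.svd(Z)
        assert abs(np.corrcoef(u, U[:, 0])[0, 1]) > 0.999
        assert abs(np.corrcoef(v, Vt[0])[0, 1]) > 0.999
        assert abs(d - S[0]) < 1e-6 * S[0]

    def test_diagonal_axis_aligned(self):
        u, v, d, _ = fit_component(np.diag([5.0, 1.0]), np.sqrt(2), np.sqrt(2))
        assert np.allclose(np.abs(u), [1, 0], atol=1e-8)
        assert np.allclose(np.abs(v), [1, 0], atol=1e-8)
        assert abs(d - 5.0) < 1e-10

    def test_objective_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(40, 25))
        _, _, _, log = fit_component(Z, 0.4 * np.sqrt(40), 0.6 * np.sqrt(25))
        obj = np.array(log["objective"])
        assert np.all(np.diff(obj) >= -1e-10)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_component(np.zeros((3, 3)), 1.0, 1.0)


class TestFitScca:
    def test_planted_single_dimension_recovery(self):
        """n=400, 200 edge features, 30 items, sigma=3: first variate ~ truth."""
        cohort = generate_cohort(
            CohortConfig(
                n_subjects=400, n_nodes=21, n_items=30, n_latent=1,
                effect_scales=(3.0,), seed=17,
            )
        )
        fm, X, Y = prepare_views(cohort)
        assert fm.n_features == 210
        model = fit_scca(X, Y, SccaParams(c1_frac=0.4, c2_frac=0.5, n_components=1))
        report = score_recovery(cohort.truth, model, fm.feature_index)
        assert report["recovery"].iloc[0] >= 0.9

    def test_deflation_exhausts_rank_one(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=300)
        X = np.outer(t, rng.normal(size=20)) + 1e-9 * rng.normal(size=(300, 20))
        Y = np.outer(t, rng.normal(size=8)) + 1e-9 * rng.normal(size=(300, 8))
        model = fit_scca(X, Y, SccaParams(n_components=2))
        d = model.singular_values
        assert d[1] < 1e-6 * d[0]

    def test_independent_noise_gives_weak_first_correlation(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(200, 40)), rng.normal(size=(200, 12))
        model = fit_scca(X, Y, SccaParams(c1_frac=0.5, c2_frac=0.5))
        assert model.variates[0].r < 0.6

    def test_deterministic(self, small_views):
        _, X, Y = small_views
        params = SccaParams(c1_frac=0.4, c2_frac=0.6, n_components=3)
        m1, m2 = fit_scca(X, Y, params), fit_scca(X, Y, params)
        assert np.array_equal(m1.U, m2.U)
        assert np.array_equal(m1.V, m2.V)

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="subject"):
            fit_scca(rng.normal(size=(10, 3)), rng.normal(size=(11, 3)), SccaParams())

    def test_sparsity_monotone_in_c1(self, small_views):
        _, X, Y = small_views
        supports = []
        for frac in [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]:
            model = fit_scca(X, Y, SccaParams(c1_frac=frac, c2_frac=0.5))
            supports.append(int(np.sum(model.variates[0].u != 0)))
        assert all(a >= b for a, b in zip(supports, supports[1:]))

    def test_loading_norm_constraints_hold(self, small_views):
        _, X, Y = small_views
        p, q = X.shape[1], Y.shape[1]
        for c1, c2 in [(0.3, 0.7), (0.6, 0.2)]:
            model = fit_scca(X, Y, SccaParams(c1_frac=c1, c2_frac=c2, n_components=2))
            for cv in model.variates:
                assert np.linalg.norm(cv.u) <= 1 + 1e-6
                assert np.linalg.norm(cv.v) <= 1 + 1e-6
                assert np.sum(np.abs(cv.u)) <= max(1, c1 * np.sqrt(p)) + 1e-6
                assert np.sum(np.abs(cv.v)) <= max(1, c2 * np.sqrt(q)) + 1e-6

    def test_sign_convention_dominant_clinical_loading_positive(self, small_views):
        _, X, Y = small_views
        model = fit_scca(X, Y, SccaParams(c1_frac=0.5, c2_frac=0.5, n_components=2))
        for cv in model.variates:
            assert cv.v[np.argmax(np.abs(cv.v))] >= 0

    def test_joint_sign_flip_leaves_summaries_unchanged(self, small_views):
        """r, d and covariance shares are invariant to flipping (u, v) jointly."""
        _, X, Y = small_views
        model = fit_scca(X, Y, SccaParams(c1_frac=0.5, c2_frac=0.5, n_components=2))
        cv = model.variates[0]
        r_flipped = np.corrcoef(X @ (-cv.u), Y @ (-cv.v))[0, 1]
        assert abs(r_flipped - cv.r) < 1e-12


class TestCovarianceExplained:
    def test_fractions_sum_to_one(self, small_views):
        _, X, Y = small_views
        model = fit_scca(X, Y, SccaParams(c1_frac=0.6, c2_frac=0.6, n_components=4))
        assert abs(covariance_explained(model).sum() - 1) < 1e-12
        assert abs(covariance_explained(model, squared=True).sum() - 1) < 1e-12

    def test_rank_one_concentrates_on_first(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=200)
        X = np.outer(t, rng.normal(size=10)) + 1e-8 * rng.normal(size=(200, 10))
        Y = np.outer(t, rng.normal(size=6)) + 1e-8 * rng.normal(size=(200, 6))
        model = fit_scca(X, Y, SccaParams(n_components=2))
        fracs = covariance_explained(model)
        assert fracs[0] > 0.999 and fracs[1] < 1e-3
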