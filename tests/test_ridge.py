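"""Ridge full-model, sub-model and projected-beta1 estimators, and CV for k."""

import numpy as np
import pytest

from shrinkridge import (
    LongitudinalDataset,
    RankDeficiencyError,
    RidgeConfig,
    ValidationError,
    build_marginal_covariance,
    gls_fit,
    ridge_full,
    ridge_full_beta1,
    ridge_submodel,
    select_k,
)
from conftest import dense_V, make_dataset


def whitened(data, vs):
    dense = dense_V(data, vs)
    L = np.linalg.cholesky(dense)
    Xw = np.linalg.solve(L, data.X)
    yw = np.linalg.solve(L, data.y)
    return Xw, yw


class TestRidgeFull:
    def test_k_zero_is_gls(self, small_problem):
        data, _, _, V = small_problem
        np.testing.assert_allclose(ridge_full(data, V, 0.0),
                                   gls_fit(data, V), atol=1e-9)

    def test_large_k_shrinks_to_zero(self, small_problem):
        data, _, _, V = small_problem
        assert np.max(np.abs(ridge_full(data, V, 1e8))) < 1e-6

    def test_matches_dense_inverse_oracle(self, rng):
        data, _, vs = make_dataset(rng, n=4, ni=3, p1=1, p2=2)
        V = build_marginal_covariance(data, vs)
        Vi = np.linalg.inv(dense_V(data, vs))
        k = 1.0
        oracle = np.linalg.solve(data.X.T @ Vi @ data.X + k * np.eye(data.p),
                                 data.X.T @ Vi @ data.y)
        np.testing.assert_allclose(ridge_full(data, V, k), oracle, atol=1e-9)

    def test_dual_solve_matches_primal_formula_when_p_gt_N(self, rng):
        data, _, vs = make_dataset(rng, n=3, ni=3, p1=2, p2=12)
        V = build_marginal_covariance(data, vs)
        Xw, yw = whitened(data, vs)
        k = 0.5
        oracle = np.linalg.solve(Xw.T @ Xw + k * np.eye(data.p), Xw.T @ yw)
        np.testing.assert_allclose(ridge_full(data, V, k), oracle, atol=1e-8)

    def test_k_zero_singular_raises(self, rng):
        data, _, vs = make_dataset(rng, n=2, ni=2, p1=2, p2=4)  # p > N
        V = build_marginal_covariance(data, vs)
        with pytest.raises(RankDeficiencyError):
            ridge_full(data, V, 0.0)

    def test_monotone_shrinkage_in_whitened_norm(self, rng):
        data, _, vs = make_dataset(rng, n=6, ni=4, p1=3, p2=3)
        V = build_marginal_covariance(data, vs)
        norms = [np.linalg.norm(ridge_full(data, V, k))
                 for k in [0.0, 0.1, 1.0, 10.0, 100.0]]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


class TestRidgeSubmodel:
    def test_no_sparse_block_equals_full(self, rng):
        data, _, vs = make_dataset(rng, p1=3, p2=1)
        data.x1_idx, data.x2_idx = np.arange(4), np.arange(4, 4)
        V = build_marginal_covariance(data, vs)
        np.testing.assert_allclose(ridge_submodel(data, V, 0.7).beta1,
                                   ridge_full(data, V, 0.7), atol=1e-10)

    def test_matches_dense_formula_oracle(self, rng):
        data, _, vs = make_dataset(rng)
        V = build_marginal_covariance(data, vs)
        Vi = np.linalg.inv(dense_V(data, vs))
        X1, k = data.X1, 2.0
        oracle = np.linalg.solve(X1.T @ Vi @ X1 + k * np.eye(data.p1),
                                 X1.T @ Vi @ data.y)
        np.testing.assert_allclose(ridge_submodel(data, V, k).beta1, oracle,
                                   atol=1e-9)

    def test_orthogonal_sparse_block_changes_nothing(self, rng):
        # X2 orthogonal (in the V^{-1} metric) to X1 and Y: RSM block of the
        # full ridge fit equals RSM for every k
        data, _, vs = make_dataset(rng, n=8, ni=3, p1=2, p2=2)
        Xw, yw = whitened(data, vs)
        Q, _ = np.linalg.qr(np.column_stack([Xw[:, :2], yw]))
        proj = np.eye(data.N) - Q @ Q.T
        Xw2_orth = proj @ data.X[:, 2:]  # construct in whitened coords
        L = np.linalg.cholesky(dense_V(data, vs))
        data.X[:, 2:] = L @ Xw2_orth
        V = build_marginal_covariance(data, vs)
        for k in [0.0, 1.0]:
            full = ridge_full(data, V, k)
            np.testing.assert_allclose(ridge_submodel(data, V, k).beta1,
                                       full[:2], atol=1e-8)


class TestRidgeFullBeta1:
    def test_frisch_waugh_equals_gls_block_at_k0(self, rng):
        data, _, vs = make_dataset(rng, n=10, ni=4, p1=2, p2=4)
        V = build_marginal_covariance(data, vs)
        res = ridge_full_beta1(data, V, 0.0)
        np.testing.assert_allclose(res.beta1, gls_fit(data, V)[:2], atol=1e-8)

    def test_matches_dense_pinv_oracle_when_p2_gt_N(self, rng):
        data, _, vs = make_dataset(rng, n=3, ni=3, p1=2, p2=15)
        V = build_marginal_covariance(data, vs)
        Xw, yw = whitened(data, vs)
        X1w, X2w = Xw[:, :2], Xw[:, 2:]
        M = np.eye(data.N) - X2w @ np.linalg.pinv(X2w.T @ X2w) @ X2w.T
        k = 0.3
        oracle = np.linalg.solve(X1w.T @ M @ X1w + k * np.eye(2),
                                 X1w.T @ M @ yw)
        res = ridge_full_beta1(data, V, k, inner_inverse="pinv")
        np.testing.assert_allclose(res.beta1, oracle, atol=1e-8)

    def test_ridge_inner_inverse_matches_dense_oracle(self, rng):
        data, _, vs = make_dataset(rng, n=3, ni=3, p1=2, p2=15)
        V = build_marginal_covariance(data, vs)
        Xw, yw = whitened(data, vs)
        X1w, X2w = Xw[:, :2], Xw[:, 2:]
        k = 0.3
        M = np.eye(data.N) - X2w @ np.linalg.solve(
            X2w.T @ X2w + k * np.eye(15), X2w.T)
        oracle = np.linalg.solve(X1w.T @ M @ X1w + k * np.eye(2),
                                 X1w.T @ M @ yw)
        res = ridge_full_beta1(data, V, k, inner_inverse="ridge")
        np.testing.assert_allclose(res.beta1, oracle, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        data, _, vs = make_dataset(rng, n=5, ni=3)
        V = build_marginal_covariance(data, vs)
        ref = {f.__name__: f(data, V, 0.8).beta1 if f is not ridge_full
               else f(data, V, 0.8)
               for f in (ridge_full, ridge_submodel, ridge_full_beta1)}
        blocks = [tuple(b) for b in data.iter_subjects()]
        order = rng.permutation(len(blocks))
        perm = LongitudinalDataset.from_blocks([blocks[i] for i in order],
                                               data.x1_idx, data.x2_idx)
        Vp = build_marginal_covariance(perm, vs)
        np.testing.assert_allclose(ridge_full(perm, Vp, 0.8),
                                   ref["ridge_full"], atol=1e-9)
        np.testing.assert_allclose(ridge_submodel(perm, Vp, 0.8).beta1,
                                   ref["ridge_submodel"], atol=1e-9)
        np.testing.assert_allclose(ridge_full_beta1(perm, Vp, 0.8).beta1,
                                   ref["ridge_full_beta1"], atol=1e-9)


class TestSelectK:
    def test_singleton_grid_returned(self, small_problem):
        data, _, _, V = small_problem
        cfg = RidgeConfig(k_grid=[3.14], cv_folds=2)
        assert select_k(data, V, cfg) == 3.14

    def test_duplicate_grid_entries_first_wins(self, small_problem):
        data, _, _, V = small_problem
        cfg = RidgeConfig(k_grid=[0.5, 0.5, 0.5], cv_folds=2)
        assert select_k(data, V, cfg) == 0.5

    def test_too_few_subjects_rejected(self, small_problem):
        data, _, _, V = small_problem
        with pytest.raises(ValidationError):
            select_k(data, V, RidgeConfig(cv_folds=data.n + 1))

    def test_pure_noise_prefers_heavy_shrinkage(self):
        # beta = 0: the large grid value should win almost always
        hits = 0
        n_seeds = 30
        for s in range(n_seeds):
            r = np.random.default_rng(1000 + s)
            data, _, vs = make_dataset(r, n=12, ni=4, p1=3, p2=3,
                                       beta=np.zeros(6))
            V = build_marginal_covariance(data, vs)
            cfg = RidgeConfig(k_grid=[0.01, 1e4], cv_folds=3, cv_seed=s)
            hits += select_k(data, V, cfg) == 1e4
        assert hits / n_seeds >= 0.9
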