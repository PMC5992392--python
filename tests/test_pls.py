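import numpy as np
import pytest

from mia.datasets import MethodParams
from mia.pls import (
    SparsityError,
    cross_validate_params,
    deflate,
    fit_multiblock,
    fit_pls_component,
    fit_smbpls_component,
    fit_snpls_component,
    make_folds,
)
from mia.preprocess import center_columns, normalized_laplacian


@pytest.fixture
def xy(rng):
    X = center_columns(rng.normal(size=(30, 12)))
    Y = center_columns(rng.normal(size=(30, 8)))
    return X, Y


class TestPlainPls:
    def test_single_column_weight_is_unit(self, rng):
        X = center_columns(rng.normal(size=(20, 1)))
        Y = center_columns(rng.normal(size=(20, 3)))
        comp = fit_pls_component(X, Y)
        assert abs(abs(comp.w[0]) - 1.0) < 1e-12

    def test_weight_equals_leading_singular_vector(self, xy):
        X, Y = xy
        comp = fit_pls_component(X, Y)
        u_svd = np.linalg.svd(X.T @ Y)[0][:, 0]
        assert np.abs(np.abs(comp.w) - np.abs(u_svd)).max() < 1e-6

    def test_loading_deflation_orthogonality(self, xy):
        X, Y = xy
        comp = fit_pls_component(X, Y)
        t, p = comp.t, comp.p_list[0]
        assert np.abs((X - np.outer(t, p)).T @ t).max() < 1e-8

    def test_unit_norms(self, xy):
        X, Y = xy
        comp = fit_pls_component(X, Y)
        assert abs(np.linalg.norm(comp.w) - 1) < 1e-8
        assert abs(np.linalg.norm(comp.q) - 1) < 1e-8

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            fit_pls_component(np.zeros((10, 3)), np.zeros((10, 2)))


class TestDeflate:
    def test_exact_rank_one_gives_zero(self, rng):
        t = rng.normal(size=10)
        p = rng.normal(size=5)
        X = np.outer(t, p)
        Y = rng.normal(size=(10, 3))
        Xd, _ = deflate(X, Y, t, "regression")
        assert np.abs(Xd).max() < 1e-10

    def test_regression_mode_orthogonalizes_response(self, rng):
        X, Y = rng.normal(size=(15, 6)), rng.normal(size=(15, 4))
        t = rng.normal(size=15)
        _, Yd = deflate(X, Y, t, "regression")
        assert np.abs(Yd.T @ t).max() < 1e-10

    def test_symmetric_mode_orthogonalizes_each_side_by_its_score(self, rng):
        X, Y = rng.normal(size=(15, 6)), rng.normal(size=(15, 4))
        t, u = rng.normal(size=15), rng.normal(size=15)
        Xd, Yd = deflate(X, Y, t, "symmetric", u=u)
        assert np.abs(Xd.T @ t).max() < 1e-10
        assert np.abs(Yd.T @ u).max() < 1e-10

    def test_zero_score_rejected(self, rng):
        with pytest.raises(ValueError, match="zero score"):
            deflate(np.ones((5, 2)), np.ones((5, 2)), np.zeros(5))


class TestSmbpls:
    def test_zero_penalty_single_block_equals_plain_pls(self, xy):
        X, Y = xy
        plain = fit_pls_component(X, Y)
        sparse = fit_smbpls_component([X], Y, 0.0, 0.0, tol=1e-12)
        assert np.abs(sparse.w_list[0] - plain.w).max() < 1e-6
        assert np.abs(sparse.q - plain.q).max() < 1e-6

    def test_extreme_fraction_keeps_single_coordinate(self, xy):
        X, Y = xy
        comp = fit_smbpls_component([X], Y, 0.99, 0.0)
        assert np.count_nonzero(comp.w_list[0]) == 1

    def test_block_weights_unit_norm_and_super_score_identity(self, rng):
        blocks = [center_columns(rng.normal(size=(25, 7))) for _ in range(3)]
        Y = center_columns(rng.normal(size=(25, 5)))
        comp = fit_smbpls_component(blocks, Y, 0.1, 0.1)
        assert abs(np.linalg.norm(comp.b) - 1) < 1e-8
        t = sum(bi * ti for bi, ti in zip(comp.b, comp.t_list))
        assert np.abs(comp.t - t).max() < 1e-10

    def test_support_non_increasing_in_lambda(self, xy):
        X, Y = xy
        sizes = []
        for lam in (0.0, 0.1, 0.2, 0.4, 0.6, 0.8):
            comp = fit_smbpls_component([X], Y, lam, 0.0, u0=Y[:, 0])
            sizes.append(np.count_nonzero(comp.w_list[0]))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_overly_aggressive_sparsity_names_the_block(self, xy):
        X, Y = xy
        with pytest.raises(SparsityError, match="block 1"):
            fit_smbpls_component([X], Y, 1.0, 0.0)


class TestSnpls:
    def test_zero_penalties_equal_plain_pls(self, xy):
        X, Y = xy
        plain = fit_pls_component(X, Y)
        comp = fit_snpls_component(X, Y, None, None, 0, 0, 0, 0, tol=1e-12)
        assert np.abs(comp.w_list[0] - plain.w).max() < 1e-6

    def test_warm_start_is_the_unconstrained_solution(self, xy):
        """One inner round from the warm start changes nothing when all
        penalties are zero: the start already is the fixed point."""
        X, Y = xy
        plain = fit_pls_component(X, Y)
        comp = fit_snpls_component(X, Y, None, None, 0, 0, 0, 0, max_iter=1)
        assert np.abs(comp.w_list[0] - plain.w).max() < 1e-6

    def test_network_smoothing_shrinks_linked_duplicate_gap(self, rng):
        X = rng.normal(size=(40, 10))
        X[:, 1] = X[:, 0] + rng.normal(0, 0.05, 40)
        X = center_columns(X)
        Y = center_columns(X[:, :3] @ rng.normal(size=(3, 4)) + rng.normal(0, 0.1, (40, 4)))
        A = np.zeros((10, 10))
        A[0, 1] = A[1, 0] = 1.0
        L = normalized_laplacian(A)
        gaps = []
        for gamma in (0.0, 1.0, 10.0, 100.0):
            comp = fit_snpls_component(X, Y, L, None, gamma, 0, 0, 0)
            w = comp.w_list[0]
            gaps.append(abs(abs(w[0]) - abs(w[1])))
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < gaps[0]


class TestCrossValidation:
    def test_folds_partition_all_samples(self):
        folds = make_folds(23, 5, seed=3)
        allidx = np.concatenate(folds)
        assert len(allidx) == 23
        assert len(np.unique(allidx)) == 23

    def test_fold_with_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="< 2 samples"):
            make_folds(5, 4, seed=0)

    def test_single_candidate_returned_unchanged(self, rng):
        blocks = [rng.normal(size=(20, 6))]
        Y = rng.normal(size=(20, 4))
        params = MethodParams(
            n_modules=1, lambda_grid=(0.3,), mu_grid=(0.1,),
            gamma1_grid=(0.0,), gamma2_grid=(0.0,), seed=0,
        )
        selected, table, folds = cross_validate_params("smbpls", blocks, Y, params)
        assert selected == {"lambda": 0.3, "mu": 0.1, "gamma1": 0.0, "gamma2": 0.0}
        assert len(table) == 1 and len(folds) == params.n_folds

    def test_selected_candidate_beats_grid_extremes_on_sparse_truth(self):
        """With a truly sparse planted weight vector, the CV winner's
        held-out score should match or beat both the dense (lambda=0)
        and the maximally sparse extreme of the grid."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            m, n = 40, 30
            w_true = np.zeros(n)
            w_true[:4] = rng.choice([-1, 1], 4) * rng.uniform(1, 2, 4)
            X = rng.normal(size=(m, n))
            Y = np.outer(X @ w_true, rng.uniform(0.5, 1.5, 3)) + rng.normal(0, 1.0, (m, 3))
            params = MethodParams(
                n_modules=1, lambda_grid=(0.0, 0.4, 0.9), mu_grid=(0.0,), seed=seed
            )
            selected, table, _ = cross_validate_params("smbpls", [X], Y, params)
            scores = {row["lambda"]: row["score"] for row in table}
            if scores[selected["lambda"]] >= max(scores[0.0], scores[0.9]) - 1e-12:
                wins += 1
        assert wins >= 0.8 * n_rep


class TestFitMultiblock:
    def test_single_component_equals_direct_fit(self, rng):
        X = rng.normal(size=(25, 10))
        Y = rng.normal(size=(25, 6))
        params = MethodParams(n_modules=1, lambda_grid=(0.2,), mu_grid=(0.1,), seed=0)
        model = fit_multiblock("smbpls", [X], Y, params)
        direct = fit_smbpls_component(
            [center_columns(X)], center_columns(Y), 0.2, 0.1
        )
        assert np.abs(model.components[0].w_list[0] - direct.w_list[0]).max() < 1e-10

    def test_successive_super_scores_decorrelate(self, rng):
        X = rng.normal(size=(40, 15))
        Y = rng.normal(size=(40, 8))
        params = MethodParams(n_modules=2, lambda_grid=(0.1,), mu_grid=(0.1,), seed=1)
        model = fit_multiblock("smbpls", [X], Y, params)
        t1, t2 = model.components[0].t, model.components[1].t
        corr = np.corrcoef(t1, t2)[0, 1]
        assert abs(corr) <= 0.2

    def test_unit_norms_hold_for_every_component(self, rng):
        blocks = [rng.normal(size=(30, 8)), rng.normal(size=(30, 6))]
        Y = rng.normal(size=(30, 5))
        params = MethodParams(n_modules=3, lambda_grid=(0.2,), mu_grid=(0.1,), seed=2)
        model = fit_multiblock("smbpls", blocks, Y, params)
        for comp in model.components:
            for w in comp.w_list:
                assert abs(np.linalg.norm(w) - 1) < 1e-8
            assert abs(np.linalg.norm(comp.q) - 1) < 1e-8
            assert abs(np.linalg.norm(comp.b) - 1) < 1e-8

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown PLS method"):
            fit_multiblock(
                "pcr", [rng.normal(size=(10, 4))], rng.normal(size=(10, 2)),
                MethodParams(n_modules=1, lambda_grid=(0.1,), mu_grid=(0.1,)),
            )

    def test_recovers_planted_comodules_without_noise(self, noiseless_bundle):
        """With five components on (almost) noiseless data, at least four
        embedded co-modules are matched with high overlap."""
        from mia.evaluation import best_match, run_smbpls_on_bundle

        params = MethodParams(n_modules=5, lambda_grid=(0.25,), mu_grid=(0.15,), seed=0)
        modules, _ = run_smbpls_on_bundle(noiseless_bundle, params)
        scores = sorted(
            (best_match(mod, noiseless_bundle.G2)[1] for mod in modules), reverse=True
        )
        assert sum(s >= 0.8 for s in scores) >= 4
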