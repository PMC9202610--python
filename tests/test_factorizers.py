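"""Extractor contracts: recovery oracles, invariants, cross-checks."""

import numpy as np
import pytest
from sklearn.decomposition import NMF as SkNMF
from sklearn.decomposition import PCA as SkPCA
from sklearn.decomposition import FastICA as SkFastICA

import synergybench as sb
from synergybench.factorizers import AutoencoderExtractor, NMFExtractor, PCAExtractor
from synergybench.metrics import (compute_vaf, match_components,
                                  principal_angles,
                                  synergy_vector_similarity)

from conftest import make_noiseless_trial, make_separated_truth


class TestPCA:
    def test_exact_rank_k_recovery(self, noiseless_trial):
        res = sb.extract_pca(noiseless_trial.M, 4)
        assert compute_vaf(noiseless_trial.M, res.reconstruct()) == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_components(self, noisy_trial):
        res = sb.extract_pca(noisy_trial.M, 4)
        np.testing.assert_allclose(res.W_hat.T @ res.W_hat, np.eye(4), atol=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        # covariance-eigenvector oracle on a 5 x 50 random matrix
        rng = np.random.default_rng(0)
        M = rng.random((5, 50))
        res = sb.extract_pca(M, 4)
        Xc = M - M.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        top = evecs[:, np.argsort(evals)[::-1][:4]]
        dots = np.abs(np.sum(top * res.W_hat, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_agrees_with_sklearn(self, noisy_trial):
        ours = sb.extract_pca(noisy_trial.M, 4)
        theirs = SkPCA(n_components=4).fit(noisy_trial.M.T)
        dots = np.abs(np.sum(theirs.components_.T * ours.W_hat, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_vaf_monotone_in_k(self, noisy_trial):
        vafs = [compute_vaf(noisy_trial.M, sb.extract_pca(noisy_trial.M, k).reconstruct())
                for k in range(1, 10)]
        assert np.all(np.diff(vafs) >= -1e-12)

    def test_k_too_large_rejected(self, noisy_trial):
        with pytest.raises(ValueError):
            sb.extract_pca(noisy_trial.M, 11)


@pytest.fixture(scope="module")
def bss_fixture():
    # 6 x 1000 noiseless mixture of 4 independent exponential sources
    rng = np.random.default_rng(1)
    S = rng.exponential(1.0, size=(4, 1000))
    A = rng.random((6, 4))
    return A, S, A @ S


class TestICA:
    def test_blind_source_recovery(self, bss_fixture):
        A, S, M = bss_fixture
        res = sb.extract_ica(M, 4, seed=3)
        match = match_components(A / np.linalg.norm(A, axis=0), res.W_hat)
        assert synergy_vector_similarity(match) >= 0.95

    def test_estimated_sources_uncorrelated(self, noisy_trial):
        # whitening contract: recovered sources have diagonal sample covariance
        res = sb.extract_ica(noisy_trial.M, 4, seed=0)
        C = np.cov(res.C_hat)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(C)).max()

    def test_deterministic_under_seed(self, noisy_trial):
        a = sb.extract_ica(noisy_trial.M, 4, seed=5)
        b = sb.extract_ica(noisy_trial.M, 4, seed=5)
        np.testing.assert_array_equal(a.W_hat, b.W_hat)

    def test_agrees_with_sklearn_fastica(self, bss_fixture):
        # independent implementation recovers the same mixing directions
        A, S, M = bss_fixture
        ours = sb.extract_ica(M, 4, seed=3)
        sk = SkFastICA(n_components=4, fun="cube", whiten="unit-variance",
                       random_state=0, max_iter=1000).fit(M.T)
        A_sk = sk.mixing_ / np.linalg.norm(sk.mixing_, axis=0)
        match = match_components(A_sk, ours.W_hat)
        assert synergy_vector_similarity(match) >= 0.95

    def test_reconstruction_equals_pca_projection(self, noisy_trial):
        # rotation cancels in the reconstruction: ICA's rank-k fit equals PCA's
        ica = sb.extract_ica(noisy_trial.M, 4, seed=2)
        pca = sb.extract_pca(noisy_trial.M, 4)
        np.testing.assert_allclose(ica.reconstruct(), pca.reconstruct(), atol=1e-8)


class TestFA:
    def test_df_bound_rejects_six_channels(self):
        M = np.random.default_rng(2).random((6, 200))
        with pytest.raises(ValueError, match=r"\(m-k\)\^2-\(m\+k\)|not identified"):
            sb.extract_fa(M, 4)

    def test_df_bound_accepts_eight_channels(self, ):
        truth = make_separated_truth(8, 4, seed=3)
        M = truth.W @ truth.C + 0.05 * np.abs(np.random.default_rng(3).standard_normal((8, 1000)))
        res = sb.extract_fa(M, 4)
        assert res.W_hat.shape == (8, 4)

    def test_df_values(self):
        assert sb.fa_degrees_of_freedom(6, 4) == -6
        assert sb.fa_degrees_of_freedom(8, 4) == 4

    def test_loading_subspace_recovery(self):
        # parameter-recovery oracle: 10 variables, 3 factors, unique var 0.1
        rng = np.random.default_rng(4)
        L = rng.standard_normal((10, 3))
        F = rng.standard_normal((3, 2000))
        X = L @ F + np.sqrt(0.1) * rng.standard_normal((10, 2000))
        res = sb.extract_fa(X, 3)
        _, pa = principal_angles(L, res.W_hat)
        assert pa < 10.0

    def test_rotation_preserves_subspace(self, noisy_trial):
        rot = sb.extract_fa(noisy_trial.M, 4, rotation="varimax")
        unrot = sb.extract_fa(noisy_trial.M, 4, rotation=None)
        _, pa = principal_angles(rot.W_hat, unrot.W_hat)
        assert pa < 1e-4


class TestNMF:
    def test_nonnegative_outputs(self, noisy_trial):
        res = sb.extract_nmf(noisy_trial.M, 4, seed=0)
        assert res.W_hat.min() >= 0
        assert res.C_hat.min() >= 0
        assert res.reconstruct().min() >= 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sb.extract_nmf(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)

    def test_objective_trace_monotone_over_seeds(self):
        # numerical verification of multiplicative-update monotonicity
        rng = np.random.default_rng(5)
        V = rng.random((6, 100))
        for seed in range(50):
            est = NMFExtractor(n_components=3, max_iter=150, n_restarts=1,
                               screen_iter=150, random_state=seed).fit(V.T)
            tr = np.asarray(est.objective_trace_)
            assert np.all(np.diff(tr) <= 1e-10 * tr[0])

    def test_exact_recovery_on_separated_truth(self):
        # solver-level oracle: well-separated synergies, independent
        # coefficients (temporally correlated envelopes limit identifiability
        # and are exercised by the noiseless-recovery benchmark check instead)
        truth = make_separated_truth(10, 4, seed=6)
        C = np.random.default_rng(6).exponential(1.0, size=(4, 1000))
        res = sb.extract_nmf(truth.W @ C, 4, seed=1)
        match = match_components(truth.W, res.W_hat)
        assert synergy_vector_similarity(match) >= 0.99

    def test_deterministic_under_seed(self, noisy_trial):
        a = sb.extract_nmf(noisy_trial.M, 4, seed=8, n_restarts=2)
        b = sb.extract_nmf(noisy_trial.M, 4, seed=8, n_restarts=2)
        np.testing.assert_array_equal(a.W_hat, b.W_hat)

    def test_objective_competitive_with_sklearn(self, noisy_trial):
        ours = sb.extract_nmf(noisy_trial.M, 4, seed=0)
        sk = SkNMF(n_components=4, solver="mu", init="random", max_iter=2000,
                   random_state=0, tol=1e-6).fit(noisy_trial.M)
        sk_obj = np.linalg.norm(noisy_trial.M - sk.transform(noisy_trial.M)
                                @ sk.components_) ** 2
        assert ours.objective <= 1.05 * sk_obj


class TestAutoencoder:
    def test_shapes_and_reconstruction_formula(self, noisy_trial):
        res, params = sb.extract_ae(noisy_trial.M, 4, seed=0, max_iter=150)
        assert res.C_hat.shape == (4, 1000)
        # coefficients are the linear encoder output; reconstruction is
        # decoder weights times coefficients plus decoder bias
        np.testing.assert_allclose(res.C_hat,
                                   params.IW @ noisy_trial.M + params.Ib[:, None])
        np.testing.assert_allclose(res.reconstruct(),
                                   params.OW @ res.C_hat + params.Ob[:, None])

    def test_deterministic_under_seed(self, noisy_trial):
        a, _ = sb.extract_ae(noisy_trial.M, 4, seed=3, max_iter=100)
        b, _ = sb.extract_ae(noisy_trial.M, 4, seed=3, max_iter=100)
        np.testing.assert_array_equal(a.W_hat, b.W_hat)

    def test_unregularized_ae_approaches_pca_mse(self):
        # a linear undercomplete AE at its optimum matches the PCA subspace
        for seed in range(3):
            trial = make_noiseless_trial(m=10, k=6, seed=20 + seed, n=300)
            M = trial.M + 0.05 * np.abs(np.random.default_rng(seed).standard_normal(trial.M.shape))
            est = AutoencoderExtractor(n_components=4, l2=0.0, sparsity_weight=0.0,
                                       init="pca", max_iter=2000, random_state=seed)
            est.fit(M.T)
            ae_mse = np.mean((est.reconstruct(M.T).T - M) ** 2)
            pca = sb.extract_pca(M, 4)
            pca_mse = np.mean((pca.reconstruct() - M) ** 2)
            assert ae_mse <= 1.05 * pca_mse
            assert ae_mse >= pca_mse - 1e-9


class TestSharedContract:
    def test_all_methods_same_shapes(self, noisy_trial):
        M = noisy_trial.M
        results = {
            "PCA": sb.extract_pca(M, 4),
            "ICA": sb.extract_ica(M, 4, seed=0),
            "FA": sb.extract_fa(M, 4),
            "NMF": sb.extract_nmf(M, 4, seed=0, n_restarts=3),
            "AE": sb.extract_ae(M, 4, seed=0, max_iter=150)[0],
        }
        for name, res in results.items():
            assert res.method == name
            assert res.W_hat.shape == (10, 4)
            assert res.C_hat.shape == (4, 1000)
            assert res.offset.shape == (10,)
            assert np.all(np.isfinite(res.reconstruct()))

    def test_sklearn_estimator_api(self, noisy_trial):
        # estimators compose with sklearn conventions
        est = PCAExtractor(n_components=3)
        params = est.get_params()
        assert params["n_components"] == 3
        est.set_params(n_components=4).fit(noisy_trial.M.T)
        H = est.transform(noisy_trial.M.T)
        assert H.shape == (1000, 4)
        X_hat = est.inverse_transform(H)
        assert X_hat.shape == (1000, 10)
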