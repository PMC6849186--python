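"""Dimension-reduction correctness against dense oracles and invariants."""

import numpy as np
import pytest
import scipy.linalg

from screenflow.chunked import column_moments, standardize
from screenflow.dimred import (
    apply_feature_map,
    fit_factor_analysis,
    fit_ica,
    fit_kpca,
    fit_lda,
    fit_pca,
    fourier_feature_map,
)
from screenflow.errors import DataError
from screenflow.simdata import simulate_factors

from conftest import make_table

CHUNKINGS = [1, 17, 64, 300]


class TestPCA:
    def test_degenerate_rank_line(self, rng):
        x = rng.normal(size=500)
        t = make_table(np.c_[x, 2 * x], chunk_rows=41)
        res = fit_pca(t, 2)
        shares = res.extra["all_variance_shares"]
        assert shares[0] == pytest.approx(1.0, abs=1e-10)
        assert shares[1] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("chunk_rows", CHUNKINGS)
    def test_matches_dense_eigensolver(self, rng, chunk_rows):
        x = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        res = fit_pca(make_table(x, chunk_rows=chunk_rows), 5)
        ev, vecs = np.linalg.eigh(np.cov(x.T, bias=True))
        order = np.argsort(ev)[::-1]
        ev, vecs = ev[order], vecs[:, order]
        for j in range(5):  # align oracle signs to the package convention
            i = np.argmax(np.abs(vecs[:, j]))
            if vecs[i, j] < 0:
                vecs[:, j] *= -1
        np.testing.assert_allclose(res.extra["eigenvalues"], ev, atol=1e-8)
        np.testing.assert_allclose(res.loadings, vecs, atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(120, 4)) + 5.0
        res = fit_pca(make_table(x, chunk_rows=30), 4)
        rec = res.transformed.materialize() @ res.loadings.T + res.extra["mean"]
        np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_variance_shares_sum_to_one_at_full_rank(self, rng):
        res = fit_pca(make_table(rng.normal(size=(90, 4))), 4)
        assert res.extra["variance_shares"].sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.extra["variance_shares"]) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        res = fit_pca(make_table(rng.normal(size=(90, 6))), 3)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(3), atol=1e-8
        )

    def test_k_above_features_errors(self, rng):
        with pytest.raises(DataError):
            fit_pca(make_table(rng.normal(size=(10, 3))), 4)


class TestFactorAnalysis:
    def test_covariance_recovery(self):
        t, w, _ = simulate_factors(2000, 6, 2, noise=0.1, seed=3,
                                   chunk_rows=257)
        model, _ = fit_factor_analysis(t, 2, max_iter=200)
        fitted = model.loadings @ model.loadings.T + np.diag(model.psi)
        truth = w @ w.T + 0.1**2 * np.eye(6)
        rel = np.linalg.norm(fitted - truth) / np.linalg.norm(truth)
        assert rel < 0.1

    def test_loglik_trace_non_decreasing(self, rng):
        t = make_table(rng.normal(size=(150, 5)), chunk_rows=37)
        model, _ = fit_factor_analysis(t, 2, max_iter=30)
        assert np.all(np.diff(model.loglik_trace) >= -1e-8)

    def test_heywood_case_hits_noise_floor_without_failure(self):
        # exactly low-rank data: the ML noise variance is 0, the floor binds
        t, w, _ = simulate_factors(800, 4, 3, noise=1e-6, seed=2)
        model, res = fit_factor_analysis(t, 3, max_iter=50)
        assert np.all(model.psi >= 1e-6)
        assert np.all(np.isfinite(model.loglik_trace))

    def test_convergence_flag_contract(self):
        t, _, _ = simulate_factors(500, 5, 2, noise=0.3, seed=4)
        model, _ = fit_factor_analysis(t, 2, max_iter=500, tol=1e-4)
        assert model.converged
        gains = np.diff(model.loglik_trace)
        assert gains[-1] < 1e-4

    def test_transformed_is_posterior_mean(self):
        t, _, _ = simulate_factors(400, 5, 2, noise=0.2, seed=6)
        model, res = fit_factor_analysis(t, 2)
        w, psi = model.loadings, model.psi
        beta = np.linalg.inv(
            np.eye(2) + w.T @ (w / psi[:, None])
        ) @ (w / psi[:, None]).T
        expected = (t.materialize() - model.mean) @ beta.T
        np.testing.assert_allclose(
            res.transformed.materialize(), expected, atol=1e-8
        )


class TestKernelPCA:
    def test_concentric_rings_become_linearly_separable(self, rng):
        n = 400
        theta = rng.uniform(0, 2 * np.pi, n)
        radius = np.where(np.arange(n) < n // 2, 1.0, 3.0)
        x = np.c_[radius * np.cos(theta), radius * np.sin(theta)]
        x += rng.normal(scale=0.05, size=x.shape)
        labels = (np.arange(n) >= n // 2).astype(int)
        t = standardize(make_table(x, chunk_rows=57))

        def best_threshold_accuracy(score):
            accs = [
                max(((score >= th) == labels).mean(),
                    ((score < th) == labels).mean())
                for th in np.sort(score)
            ]
            return max(accs)

        ks = fit_kpca(t, 2, n_fourier=200, gamma=1.0, seed=2)
        kpca_acc = best_threshold_accuracy(
            ks.transformed.materialize()[:, 0]
        )
        pca_acc = best_threshold_accuracy(
            fit_pca(t, 2).transformed.materialize()[:, 0]
        )
        assert kpca_acc == 1.0
        assert pca_acc < 0.9

    def test_feature_map_approximates_gaussian_kernel(self, rng):
        """Kernel error decreases monotonically with the map dimension."""
        gamma, p = 0.5, 3
        x = rng.normal(size=(100, p))
        y = rng.normal(size=(100, p))
        exact = np.exp(-gamma * np.sum((x - y) ** 2, axis=1))
        maes = []
        for d in (8, 64, 512):
            errs = []
            for seed in range(10):
                omega, b = fourier_feature_map(p, d, gamma, seed)
                approx = np.sum(
                    apply_feature_map(x, omega, b)
                    * apply_feature_map(y, omega, b), axis=1,
                )
                errs.append(np.abs(approx - exact).mean())
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]

    def test_seed_determinism(self, rng):
        t = make_table(rng.normal(size=(80, 3)), chunk_rows=19)
        a = fit_kpca(t, 2, seed=5).transformed.materialize()
        b = fit_kpca(t, 2, seed=5).transformed.materialize()
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_gamma_errors(self, rng):
        t = make_table(rng.normal(size=(20, 2)))
        with pytest.raises(DataError, match="gamma"):
            fit_kpca(t, 1, gamma=0.0, seed=0)


class TestICA:
    def test_blind_source_recovery(self, rng):
        z = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(5000, 2))
        mixing = rng.normal(size=(2, 2))
        t = make_table(z @ mixing.T, chunk_rows=333)
        res = fit_ica(t, 2, seed=1)
        corr = np.corrcoef(res.transformed.materialize().T, z.T)[:2, 2:]
        # each recovered source matches one true source up to sign
        best = sorted(np.max(np.abs(corr), axis=1))
        assert best[0] > 0.95

    def test_whitened_covariance_is_identity(self, rng):
        x = rng.normal(size=(600, 4)) @ rng.normal(size=(4, 4))
        t = make_table(x, chunk_rows=111)
        res = fit_ica(t, 3, max_iter=5, seed=0)
        xw = (x - res.extra["mean"]) @ res.extra["whitening"]
        np.testing.assert_allclose(
            np.cov(xw.T, bias=True), np.eye(3), atol=1e-6
        )

    def test_seed_determinism(self, rng):
        t = make_table(rng.uniform(size=(300, 3)), chunk_rows=71)
        a = fit_ica(t, 2, seed=9).extra["unmixing"]
        b = fit_ica(t, 2, seed=9).extra["unmixing"]
        np.testing.assert_array_equal(a, b)


class TestLDA:
    def test_two_class_direction_is_mean_difference(self, rng):
        mu2 = np.array([2.0, 1.0, -1.0])
        x = np.vstack([
            rng.normal(size=(1000, 3)),
            rng.normal(size=(1000, 3)) + mu2,
        ])
        y = np.r_[np.zeros(1000), np.ones(1000)]
        t = make_table(np.c_[x, y], names=["a", "b", "c", "lab"],
                       chunk_rows=123)
        res = fit_lda(t, "lab", 1)
        d = res.loadings[:, 0] / np.linalg.norm(res.loadings[:, 0])
        ref = mu2 / np.linalg.norm(mu2)
        assert abs(d @ ref) > 0.99

    def test_rank_bound(self, rng):
        y = np.r_[np.zeros(20), np.ones(20)]
        t = make_table(np.c_[rng.normal(size=(40, 3)), y],
                       names=["a", "b", "c", "lab"])
        with pytest.raises(DataError, match="C-1"):
            fit_lda(t, "lab", 2)

    def test_three_class_matches_dense_generalized_eigenproblem(self, rng):
        means = np.array([[0, 0, 0], [3, 0, 1], [0, 3, -1]], dtype=float)
        x = np.vstack([rng.normal(size=(200, 3)) + m for m in means])
        y = np.repeat([0.0, 1.0, 2.0], 200)
        t = make_table(np.c_[x, y], names=["a", "b", "c", "lab"],
                       chunk_rows=77)
        res = fit_lda(t, "lab", 2)

        # dense oracle: scatter matrices from the materialized data
        grand = x.mean(axis=0)
        sw = np.zeros((3, 3))
        sb = np.zeros((3, 3))
        for c in (0, 1, 2):
            xc = x[y == c]
            mu = xc.mean(axis=0)
            sw += (xc - mu).T @ (xc - mu)
            sb += len(xc) * np.outer(mu - grand, mu - grand)
        ev, vecs = scipy.linalg.eigh(sb, sw)
        oracle = vecs[:, np.argsort(ev)[::-1][:2]]
        for j in range(2):
            i = np.argmax(np.abs(oracle[:, j]))
            if oracle[i, j] < 0:
                oracle[:, j] *= -1
        np.testing.assert_allclose(res.loadings, oracle, atol=1e-6)


class TestPartitionInvariance:
    @pytest.mark.parametrize("chunk_rows", CHUNKINGS)
    def test_all_methods_invariant_to_chunking(self, rng, chunk_rows):
        x = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        y = rng.integers(0, 2, 300).astype(float)
        ref_feats = make_table(x, chunk_rows=300)
        ref_lab = make_table(np.c_[x, y],
                             names=["a", "b", "c", "d", "e", "lab"],
                             chunk_rows=300)
        feats = make_table(x, chunk_rows=chunk_rows)
        lab = make_table(np.c_[x, y],
                         names=["a", "b", "c", "d", "e", "lab"],
                         chunk_rows=chunk_rows)

        np.testing.assert_allclose(
            fit_pca(feats, 3).loadings, fit_pca(ref_feats, 3).loadings,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            fit_factor_analysis(feats, 2, max_iter=20)[0].loadings,
            fit_factor_analysis(ref_feats, 2, max_iter=20)[0].loadings,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            fit_kpca(feats, 2, seed=3).loadings,
            fit_kpca(ref_feats, 2, seed=3).loadings,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            fit_ica(feats, 2, max_iter=10, seed=3).extra["unmixing"],
            fit_ica(ref_feats, 2, max_iter=10, seed=3).extra["unmixing"],
            atol=1e-8,
        )
        np.testing.assert_allclose(
            fit_lda(lab, "lab", 1).loadings,
            fit_lda(ref_lab, "lab", 1).loadings,
            atol=1e-8,
        )
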