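"""Trans-disease model: objective pieces, gradient, fitting limits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from targetrepo.graph import cosine_similarity_matrix, graph_laplacian
from targetrepo.io import DiseaseSignature
from targetrepo.model import (LabelMatrix, TrainConfig, TransDiseaseLogistic,
                              laplacian_penalty, logistic_loss, ridge_penalty,
                              select_hyperparameters,
                              HyperparameterSelectionError)
from targetrepo.model import laplacian_penalty_sum_form
from targetrepo.evaluation import roc_auc


def random_similarity(rng, M):
    import pandas as pd
    A = rng.standard_normal((M, 8))
    sigs = [DiseaseSignature(f"d{i}", pd.Series(A[i], index=[f"g{k}" for k in range(8)]))
            for i in range(M)]
    return cosine_similarity_matrix(sigs)


class TestLossPieces:
    def test_zero_weights_give_nm_log2(self, rng):
        X = rng.standard_normal((7, 4))
        Y = (rng.random((7, 3)) < 0.3).astype(float)
        assert logistic_loss(np.zeros((4, 3)), X, Y) == pytest.approx(21 * np.log(2))

    def test_scalar_hand_value(self):
        # single pair, positive label, margin 0.5
        X = np.array([[1.0]])
        W = np.array([[0.5]])
        assert logistic_loss(W, X, np.array([[1.0]])) == \
            pytest.approx(np.log1p(np.exp(-0.5)), abs=1e-10)

    def test_label_flip_weight_negation_symmetry(self, rng):
        X = rng.standard_normal((6, 5))
        W = rng.standard_normal((5, 2))
        Y = (rng.random((6, 2)) < 0.5).astype(float)
        assert logistic_loss(W, X, Y) == pytest.approx(logistic_loss(-W, X, 1 - Y))

    def test_numerically_stable_at_huge_margins(self):
        X = np.array([[1.0]])
        assert np.isfinite(logistic_loss(np.array([[1e3]]), X, np.array([[0.0]])))

    def test_observed_mask_restricts_sum(self, rng):
        X = rng.standard_normal((5, 3))
        Y = (rng.random((5, 2)) < 0.5).astype(float)
        O = np.ones((5, 2))
        O[0, 0] = 0.0
        full = logistic_loss(np.zeros((3, 2)), X, Y)
        assert logistic_loss(np.zeros((3, 2)), X, Y, O) == \
            pytest.approx(full - np.log(2))

    def test_ridge_hand_value_and_homogeneity(self, rng):
        assert ridge_penalty(np.array([[1.0, 2.0], [3.0, 4.0]])) == pytest.approx(15.0)
        W = rng.standard_normal((4, 3))
        assert ridge_penalty(3.0 * W) == pytest.approx(9.0 * ridge_penalty(W))
        assert ridge_penalty(np.zeros((2, 2))) == 0.0

    def test_laplacian_penalty_zero_for_identity_similarity(self, rng):
        _, Ls = graph_laplacian(np.eye(3))
        assert laplacian_penalty(rng.standard_normal((5, 3)), Ls) == pytest.approx(0.0)

    def test_laplacian_penalty_zero_for_shared_weights(self):
        _, Ls = graph_laplacian(np.ones((2, 2)))
        W = np.tile(np.array([[1.0], [2.0]]), (1, 2))
        assert laplacian_penalty(W, Ls) == pytest.approx(0.0, abs=1e-12)

    def test_trace_form_equals_sum_form(self, rng):
        for _ in range(20):
            M = rng.integers(2, 7)
            S = np.maximum(random_similarity(rng, M), 0.0)
            K, Ls = graph_laplacian(S)
            W = rng.standard_normal((rng.integers(2, 9), M))
            assert laplacian_penalty(W, Ls) == \
                pytest.approx(laplacian_penalty_sum_form(W, S, K), abs=1e-9)


class TestObjectiveAndGradient:
    def _instance(self, rng, N=12, d=5, M=3):
        X = rng.standard_normal((N, d))
        Y = (rng.random((N, M)) < 0.3).astype(float)
        S = np.maximum(random_similarity(rng, M), 0.0)
        _, Ls = graph_laplacian(S)
        return TransDiseaseLogistic(X, Y, Ls)

    def test_objective_is_sum_of_components(self, rng):
        model = self._instance(rng)
        W = rng.standard_normal((5, 3))
        cfg = TrainConfig(lambda_s=0.7, lambda_r=0.3)
        expected = (logistic_loss(W, model.X, model.labels.Y)
                    + 0.7 * laplacian_penalty(W, model.Ls)
                    + 0.3 * ridge_penalty(W))
        assert model.objective(W, cfg) == pytest.approx(expected)

    def test_unregularized_objective_is_the_loss(self, rng):
        model = self._instance(rng)
        W = rng.standard_normal((5, 3))
        cfg = TrainConfig(lambda_s=0.0, lambda_r=0.0)
        assert model.objective(W, cfg) == \
            pytest.approx(logistic_loss(W, model.X, model.labels.Y))

    def test_gradient_at_zero_unregularized(self, rng):
        model = self._instance(rng)
        cfg = TrainConfig(lambda_s=0.0, lambda_r=0.0)
        Yt = 2 * model.labels.Y - 1
        expected = -0.5 * model.X.T @ Yt  # sigma(0) = 1/2
        np.testing.assert_allclose(
            model.objective_gradient(np.zeros((5, 3)), cfg), expected, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        model = self._instance(rng, N=8, d=4, M=3)
        cfg = TrainConfig(lambda_s=0.6, lambda_r=0.2)
        h = 1e-5
        for _ in range(5):
            W = rng.standard_normal((4, 3))
            grad = model.objective_gradient(W, cfg)
            fd = np.zeros_like(W)
            for idx in np.ndindex(W.shape):
                Wp, Wm = W.copy(), W.copy()
                Wp[idx] += h
                Wm[idx] -= h
                fd[idx] = (model.objective(Wp, cfg) - model.objective(Wm, cfg)) / (2 * h)
            assert np.linalg.norm(fd - grad) / np.linalg.norm(grad) < 1e-6


class TestFit:
    def test_objective_trace_monotone_nonincreasing(self, rng):
        model = TransDiseaseLogistic(rng.standard_normal((30, 6)),
                                     (rng.random((30, 4)) < 0.2).astype(float))
        res = model.fit(TrainConfig())
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_separable_toy_reaches_training_auc_one(self):
        X = np.array([[2.0, 0.1], [1.5, -0.2], [-2.0, 0.3], [-1.7, 0.0]])
        Y = np.array([[1.0], [1.0], [0.0], [0.0]])
        res = TransDiseaseLogistic(X, Y).fit(TrainConfig(lambda_r=0.01, lambda_s=0.0))
        auc = roc_auc(res.predict(X).ravel(), Y.ravel()).auc
        assert auc == 1.0

    def test_ridge_limit_shrinks_weights_monotonically(self, rng):
        X = rng.standard_normal((20, 4))
        Y = (rng.random((20, 2)) < 0.4).astype(float)
        norms = []
        for lam in [0.1, 1.0, 10.0, 100.0]:
            res = TransDiseaseLogistic(X, Y).fit(
                TrainConfig(lambda_s=0.0, lambda_r=lam, tol=1e-10))
            norms.append(np.linalg.norm(res.W))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_decoupled_columns_match_independent_fits(self, rng):
        """With lambda_s = 0 each column solves its own ridge-logistic problem."""
        N, d, M = 50, 10, 4
        X = rng.standard_normal((N, d))
        Y = (rng.random((N, M)) < 0.3).astype(float)
        lam_r = 1.0
        res = TransDiseaseLogistic(X, Y).fit(
            TrainConfig(lambda_s=0.0, lambda_r=lam_r, tol=1e-14, max_iters=50000))
        for m in range(M):
            yt = 2 * Y[:, m] - 1

            def f(w):
                margin = yt * (X @ w)
                return np.logaddexp(0, -margin).sum() + 0.5 * lam_r * w @ w

            def jac(w):
                from scipy.special import expit
                return X.T @ (expit(X @ w) - Y[:, m]) + lam_r * w

            sol = minimize(f, np.zeros(d), jac=jac, method="L-BFGS-B",
                           options={"gtol": 1e-12, "ftol": 1e-15})
            np.testing.assert_allclose(res.W[:, m], sol.x, atol=1e-4)

    def test_weight_sharing_limit(self, rng):
        """S = all-ones with huge lambda_s forces identical normalized columns."""
        N, d, M = 30, 5, 3
        X = rng.standard_normal((N, d))
        Y = (rng.random((N, M)) < 0.3).astype(float)
        Y[0, :] = 1.0
        K, Ls = graph_laplacian(np.ones((M, M)))
        res = TransDiseaseLogistic(X, Y, Ls).fit(
            TrainConfig(lambda_s=1e6, lambda_r=0.1))
        Wn = res.W / np.sqrt(np.diag(K))[None, :]
        for a in range(M):
            for b in range(a + 1, M):
                assert np.linalg.norm(Wn[:, a] - Wn[:, b]) < 1e-3

    def test_predict_scores_in_unit_interval_and_monotone(self, rng):
        model = TransDiseaseLogistic(rng.standard_normal((10, 3)),
                                     (rng.random((10, 2)) < 0.5).astype(float))
        res = model.fit(TrainConfig(max_iters=50))
        s = res.predict(rng.standard_normal((6, 3)))
        assert np.all((s > 0) & (s < 1))
        # zero signature scores exactly 0.5
        np.testing.assert_allclose(res.predict(np.zeros((1, 3))), 0.5)
        # ranking by score equals ranking by linear functional
        Xn = rng.standard_normal((8, 3))
        f = Xn @ res.W
        assert np.array_equal(np.argsort(f, axis=0),
                              np.argsort(res.predict(Xn), axis=0))

    def test_save_round_trip(self, tmp_path, rng):
        import pandas as pd, json
        model = TransDiseaseLogistic(rng.standard_normal((10, 3)),
                                     (rng.random((10, 2)) < 0.5).astype(float),
                                     gene_list=["ga", "gb", "gc"])
        res = model.fit(TrainConfig(max_iters=20))
        res.save(tmp_path / "w.tsv", tmp_path / "w.json")
        W = pd.read_csv(tmp_path / "w.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(W.to_numpy(), res.W, rtol=1e-10)
        sidecar = json.loads((tmp_path / "w.json").read_text())
        assert sidecar["gene_list"] == ["ga", "gb", "gc"]
        assert len(sidecar["objective_trace"]) == res.n_iterations + 1

    def test_summary_mentions_dimensions(self, rng):
        model = TransDiseaseLogistic(rng.standard_normal((10, 3)),
                                     (rng.random((10, 2)) < 0.5).astype(float))
        text = model.fit(TrainConfig(max_iters=10)).summary()
        assert "targets (N):          10" in text
        assert "diseases (M):         2" in text


class TestHyperparameterSelection:
    def test_single_point_grid_returns_it(self, rng):
        X = rng.standard_normal((24, 4))
        Y = (rng.random((24, 3)) < 0.3).astype(float)
        assert select_hyperparameters(X, Y, None, [(0.5, 0.5)], k=2, seed=0) == (0.5, 0.5)

    def test_all_zero_labels_raise(self, rng):
        X = rng.standard_normal((12, 4))
        Y = np.zeros((12, 3))
        with pytest.raises((HyperparameterSelectionError, Exception)):
            select_hyperparameters(X, Y, None, [(0.1, 0.1)], k=2, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((30, 4))
        Y = (rng.random((30, 3)) < 0.3).astype(float)
        grid = [(0.0, 0.1), (0.1, 0.1), (1.0, 1.0)]
        a = select_hyperparameters(X, Y, None, grid, k=2, seed=7)
        b = select_hyperparameters(X, Y, None, grid, k=2, seed=7)
        assert a == b

    def test_strong_disease_sharing_selects_graph_penalty(self):
        """When all diseases share one weight direction and labels are scarce,
        inner-CV selection prefers a positive graph-coupling strength."""
        import targetrepo as tr
        from targetrepo.simulate import (SyntheticSpec,
                                         simulate_disease_signatures,
                                         simulate_targets_and_labels)
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(N=60, M=6, d=30, n_clusters=1,
                                 within_cluster_similarity=0.9,
                                 positives_per_disease=3, seed=seed)
            sim = simulate_disease_signatures(spec)
            X, labels, _ = simulate_targets_and_labels(spec, sim)
            graph = tr.build_disease_graph(sim.signatures)
            lam = select_hyperparameters(X, labels, graph,
                                         [(0.0, 0.1), (1.0, 0.1)], k=3,
                                         seed=seed,
                                         config=TrainConfig(max_iters=800))
            wins += lam[0] > 0
        assert wins >= 16  # at least 80% of seeds


class TestLabelMatrix:
    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            LabelMatrix(Y=np.array([[0.5]]), target_ids=["t"], disease_ids=["d"])

    def test_rejects_unobserved_positive(self):
        with pytest.raises(ValueError, match="observed"):
            LabelMatrix(Y=np.array([[1.0]]), target_ids=["t"], disease_ids=["d"],
                        observed=np.array([[0.0]]))

    def test_from_associations(self):
        import pandas as pd
        assoc = pd.DataFrame({"target_gene": ["T1", "T2", "T1"],
                              "disease_id": ["d1", "d2", "d2"],
                              "mode": ["inhibitory", "inhibitory", "activatory"]})
        lm = LabelMatrix.from_associations(assoc, ["T1", "T2"], ["d1", "d2"],
                                           "inhibitory")
        np.testing.assert_array_equal(lm.Y, [[1, 0], [0, 1]])
        assert lm.diseases_without_positives() == []
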