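"""Objective, gradient, optimizer, boundary reductions, and baselines."""

import numpy as np
import pytest

from matsne import (
    OptimizerConfig,
    classical_tsne,
    convex_distance_tsne,
    kl_cost,
    matrix_tsne,
)
from matsne.distances import row_distance_matrix, col_distance_matrix
from matsne.embedding import gradient
from matsne.selection import kmeans_labels
from matsne.synthetic import PlantedDesign, make_scalar_data
from sklearn.metrics import adjusted_rand_score


def random_affinity(rng, n):
    A = rng.random((n, n))
    A = A + A.T
    np.fill_diagonal(A, 0.0)
    return A / A.sum()


class TestCost:
    def test_matches_double_summation_oracle(self, rng):
        I, K = 4, 3
        Pr, Pc = random_affinity(rng, I), random_affinity(rng, K)
        Y = rng.normal(size=(I, K, 2))
        alpha = 0.37
        # independent oracle: explicit loops over pairs
        def q_matrix(axis):
            n = I if axis == "row" else K
            W = np.zeros((n, n))
            for a in range(n):
                for b in range(n):
                    if a == b:
                        continue
                    if axis == "row":
                        s = sum(np.sum((Y[a, k] - Y[b, k]) ** 2) for k in range(K))
                    else:
                        s = sum(np.sum((Y[i, a] - Y[i, b]) ** 2) for i in range(I))
                    W[a, b] = 1.0 / (1.0 + s)
            return W / W.sum()

        Qr, Qc = q_matrix("row"), q_matrix("column")
        expected = 0.0
        for i in range(I):
            for j in range(I):
                if i != j and Pr[i, j] > 0:
                    expected += alpha * Pr[i, j] * np.log(Pr[i, j] / Qr[i, j])
        for k in range(K):
            for l in range(K):
                if k != l and Pc[k, l] > 0:
                    expected += (1 - alpha) * Pc[k, l] * np.log(Pc[k, l] / Qc[k, l])
        assert kl_cost(Pr, Pc, Y, alpha) == pytest.approx(expected, abs=1e-10)

    def test_cost_is_linear_in_alpha(self, rng):
        # at α=1 only the row KL remains; interior α interpolates linearly
        Pr, Pc = random_affinity(rng, 4), random_affinity(rng, 3)
        Y = rng.normal(size=(4, 3, 2))
        c0, c1, cm = (kl_cost(Pr, Pc, Y, a) for a in (0.0, 1.0, 0.25))
        assert cm == pytest.approx(0.25 * c1 + 0.75 * c0, abs=1e-12)
        assert kl_cost(Pr, Pc, Y, 1.0) == pytest.approx(
            kl_cost(Pr, rng.random((3, 3)), Y, 1.0)
        )

    def test_forced_uniform_distributions_give_zero(self):
        # I=K=2: both P and Q are forced to 0.5 off-diagonal, so KL = 0
        P2 = np.array([[0.0, 0.5], [0.5, 0.0]])
        Y = np.array([[[0.0, 0.0], [1.0, 0.0]], [[0.0, 1.0], [1.0, 1.0]]])
        assert kl_cost(P2, P2, Y, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self, rng):
        Pr, Pc = random_affinity(rng, 5), random_affinity(rng, 4)
        Y = rng.normal(size=(5, 4, 2))
        shifted = Y + np.array([3.3, -7.1])
        assert kl_cost(Pr, Pc, Y, 0.4) == pytest.approx(
            kl_cost(Pr, Pc, shifted, 0.4), abs=1e-10
        )


class TestGradient:
    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.7, 1.0])
    def test_finite_difference_check(self, alpha, rng):
        I, K = 5, 4
        Pr, Pc = random_affinity(rng, I), random_affinity(rng, K)
        Y = rng.normal(size=(I, K, 2))
        g = gradient(Pr, Pc, Y, alpha)
        eps = 1e-6
        num = np.zeros_like(Y)
        for i in range(I):
            for k in range(K):
                for c in range(2):
                    Yp, Ym = Y.copy(), Y.copy()
                    Yp[i, k, c] += eps
                    Ym[i, k, c] -= eps
                    num[i, k, c] = (
                        kl_cost(Pr, Pc, Yp, alpha) - kl_cost(Pr, Pc, Ym, alpha)
                    ) / (2 * eps)
        rel = np.max(np.abs(g - num)) / (np.max(np.abs(num)) + 1e-300)
        assert rel <= 1e-5

    def test_components_sum_to_zero(self, rng):
        Pr, Pc = random_affinity(rng, 6), random_affinity(rng, 5)
        Y = rng.normal(size=(6, 5, 2))
        g = gradient(Pr, Pc, Y, 0.5)
        np.testing.assert_allclose(g.sum(axis=(0, 1)), 0.0, atol=1e-12)

    def test_alpha_zero_kills_row_term(self, rng):
        Pr, Pc = random_affinity(rng, 4), random_affinity(rng, 4)
        Y = rng.normal(size=(4, 4, 2))
        g0 = gradient(Pr, Pc, Y, 0.0)
        g0_other_pr = gradient(random_affinity(rng, 4), Pc, Y, 0.0)
        np.testing.assert_allclose(g0, g0_other_pr, atol=1e-15)

    def test_as_printed_rescales_each_term_by_its_weight(self, rng):
        Pr, Pc = random_affinity(rng, 4), random_affinity(rng, 3)
        Y = rng.normal(size=(4, 3, 2))
        alpha = 0.3
        row_cc = gradient(Pr, Pc, Y, 1.0)  # 4·1·(row term)
        col_cc = gradient(Pr, Pc, Y, 0.0)
        printed = gradient(Pr, Pc, Y, alpha, variant="as_printed")
        expected = alpha**2 * row_cc + (1 - alpha) ** 2 * col_cc
        np.testing.assert_allclose(printed, expected, atol=1e-12)


class TestMatrixTsne:
    def test_boundary_alpha_collapses_columns(self, small_scalar_data):
        data, _ = small_scalar_data
        emb, _ = matrix_tsne(data, OptimizerConfig(alpha=1.0, iterations=50, seed=1))
        # every row's K coordinates are identical
        for k in range(data.n_cols):
            np.testing.assert_array_equal(emb.Y[:, k, :], emb.Y[:, 0, :])

    def test_determinism_bit_identical(self, small_scalar_data):
        data, _ = small_scalar_data
        cfg = OptimizerConfig(alpha=0.5, iterations=60, seed=9)
        e1, t1 = matrix_tsne(data, cfg)
        e2, t2 = matrix_tsne(data, cfg)
        np.testing.assert_array_equal(e1.Y, e2.Y)
        assert t1.costs == t2.costs

    def test_cost_descends_on_planted_data(self):
        wins = 0
        for seed in range(10):
            design = PlantedDesign.balanced(8, 9, 2, 3, separation=8, noise_sd=1, seed=seed)
            data, _ = make_scalar_data(design)
            _, trace = matrix_tsne(
                data, OptimizerConfig(alpha=0.5, iterations=300, seed=seed)
            )
            if trace.final_cost < trace.costs[0]:
                wins += 1
        assert wins >= 9

    def test_boundary_trajectory_equals_classical_on_margin(self, small_scalar_data):
        """α=1 (α=0) is exactly classical t-SNE on the row (column) margin."""
        data, _ = small_scalar_data
        cfg = OptimizerConfig(
            alpha=1.0, iterations=40, seed=4, perp_r=3.0, perp_c=3.0,
            record_trajectory=True,
        )
        emb, trace_m = matrix_tsne(data, cfg)
        _, trace_c = classical_tsne(row_distance_matrix(data), 3.0, cfg)
        for ym, yc in zip(trace_m.trajectory, trace_c.trajectory):
            np.testing.assert_allclose(ym, yc, atol=1e-10)
        cfg0 = OptimizerConfig(
            alpha=0.0, iterations=40, seed=4, perp_r=3.0, perp_c=3.0,
            record_trajectory=True,
        )
        _, trace_m0 = matrix_tsne(data, cfg0)
        _, trace_c0 = classical_tsne(col_distance_matrix(data), 3.0, cfg0)
        for ym, yc in zip(trace_m0.trajectory, trace_c0.trajectory):
            np.testing.assert_allclose(ym, yc, atol=1e-10)


class TestClassicalTsne:
    def test_equilateral_configuration_stays_equilateral(self):
        """Three mutually equidistant points embed as a near-equilateral triangle."""
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        for seed in range(5):
            # unit init scale: at the default 1e-4 scale every Student-t weight
            # is already equal, the gradient vanishes, and nothing moves
            y, _ = classical_tsne(
                D, 1.9, OptimizerConfig(iterations=400, seed=seed, init_scale=1.0)
            )
            d01 = np.linalg.norm(y[0] - y[1])
            d02 = np.linalg.norm(y[0] - y[2])
            d12 = np.linalg.norm(y[1] - y[2])
            mean = (d01 + d02 + d12) / 3
            for d in (d01, d02, d12):
                assert abs(d - mean) / mean < 0.05

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(12, 3))
        D = np.sqrt(np.sum((pts[:, None] - pts[None]) ** 2, axis=2))
        cfg = OptimizerConfig(iterations=50, seed=2)
        y1, _ = classical_tsne(D, 5.0, cfg)
        y2, _ = classical_tsne(D, 5.0, cfg)
        np.testing.assert_array_equal(y1, y2)

    def test_two_planted_clusters_recovered(self):
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = np.concatenate(
                [r.normal(0, 1, size=(10, 3)), r.normal(20, 1, size=(10, 3))]
            )
            truth = np.repeat([0, 1], 10)
            D = np.sqrt(np.sum((pts[:, None] - pts[None]) ** 2, axis=2))
            y, _ = classical_tsne(D, 5.0, OptimizerConfig(iterations=400, seed=seed))
            pred = kmeans_labels(y, 2, seed=seed)
            if adjusted_rand_score(truth, pred) == 1.0:
                wins += 1
        assert wins >= 9


class TestConvexDistanceBaseline:
    def test_alpha_one_distances_depend_only_on_rows(self, small_scalar_data):
        data, _ = small_scalar_data
        Dr = row_distance_matrix(data).D2
        n_k = data.n_cols
        delta2 = 1.0 * np.kron(Dr, np.ones((n_k, n_k)))
        # same-row elements are at distance 0
        for i in range(data.n_rows):
            block = delta2[i * n_k : (i + 1) * n_k, i * n_k : (i + 1) * n_k]
            np.testing.assert_allclose(block, 0.0, atol=1e-12)

    def test_differs_from_matrix_tsne_objective(self, small_scalar_data):
        data, _ = small_scalar_data
        cfg = OptimizerConfig(alpha=0.5, iterations=100, seed=0)
        emb, _ = matrix_tsne(data, cfg)
        y, _ = convex_distance_tsne(data, 0.5, cfg, perplexity=5.0)
        assert not np.allclose(emb.points(), y)
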