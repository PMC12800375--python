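"""Distance layer: DTW, Wasserstein, margin and element matrices vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matsne import (
    HistogramElement,
    MatrixFramedData,
    SeriesElement,
    col_distance_matrix,
    dtw,
    element_distance_matrix,
    row_distance_matrix,
    series_sq_distance,
    wasserstein,
)
from matsne.distances import element_sq_distance
from tests.conftest import random_histogram


# --- independent oracles ----------------------------------------------------


def dtw_brute(a, b, diag_weight):
    """Exhaustive enumeration of every monotone warping path (lengths <= ~7)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def rec(i, j, cost):
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, cost + diag_weight * abs(a[i + 1] - b[j + 1]))
        if i + 1 < n:
            rec(i + 1, j, cost + abs(a[i + 1] - b[j]))
        if j + 1 < m:
            rec(i, j + 1, cost + abs(a[i] - b[j + 1]))

    rec(0, 0, abs(a[0] - b[0]))
    return best[0]


def wasserstein_quadrature(h1, h2, n=1_000_000):
    """Midpoint-rule quadrature of the squared quantile-function difference."""
    t = (np.arange(n) + 0.5) / n
    q1 = np.interp(t, np.concatenate(([0.0], np.cumsum(h1.masses))), h1.bin_edges)
    q2 = np.interp(t, np.concatenate(([0.0], np.cumsum(h2.masses))), h2.bin_edges)
    return float(np.sqrt(np.mean((q1 - q2) ** 2)))


# --- DTW --------------------------------------------------------------------


class TestDTW:
    def test_single_pair_alignment(self):
        assert dtw([0.0], [3.0]) == pytest.approx(3.0)

    @pytest.mark.parametrize("step", ["symmetric1", "symmetric2"])
    def test_identical_sequences_cost_zero(self, step, rng):
        s = rng.normal(size=9)
        assert dtw(s, s, step=step) == pytest.approx(0.0, abs=1e-12)

    def test_zero_cost_warp(self):
        # [1,2,3] warps onto [1,2,2,3] at no cost by duplicating the 2
        assert dtw([1, 2, 3], [1, 2, 2, 3], "symmetric2") == pytest.approx(0.0)

    @pytest.mark.parametrize("step,w", [("symmetric1", 1.0), ("symmetric2", 2.0)])
    def test_matches_exhaustive_path_enumeration(self, step, w, rng):
        for _ in range(40):
            a = rng.integers(0, 5, size=rng.integers(1, 7)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(1, 7)).astype(float)
            assert dtw(a, b, step) == pytest.approx(dtw_brute(a, b, w), abs=1e-12)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_step_ordering(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        for step in ("symmetric1", "symmetric2"):
            assert dtw(a, b, step) == pytest.approx(dtw(b, a, step), abs=1e-9)
        assert dtw(a, b, "symmetric1") <= dtw(a, b, "symmetric2") + 1e-9

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dtw([], [1.0])


class TestSeriesDistance:
    def test_identical_elements_zero(self, rng):
        x = SeriesElement(rng.normal(size=(6, 3)))
        assert series_sq_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_single_coordinate_reduces_to_dtw_squared(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        x, y = SeriesElement(a[:, None]), SeriesElement(b[:, None])
        assert series_sq_distance(x, y) == pytest.approx(dtw(a, b) ** 2)

    def test_sums_squared_per_coordinate_costs(self, rng):
        x = SeriesElement(rng.normal(size=(5, 3)))
        y = SeriesElement(rng.normal(size=(6, 3)))
        expected = sum(dtw(x.values[:, p], y.values[:, p]) ** 2 for p in range(3))
        assert series_sq_distance(x, y) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            series_sq_distance(
                SeriesElement(np.zeros((4, 2))), SeriesElement(np.zeros((4, 3)))
            )


# --- Wasserstein ------------------------------------------------------------


class TestWasserstein:
    def test_identical_histograms_zero(self, rng):
        h = random_histogram(rng)
        assert wasserstein(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_translated_point_masses(self):
        eps = 1e-9
        h0 = HistogramElement([-eps / 2, eps / 2], [1.0])
        h2 = HistogramElement([2 - eps / 2, 2 + eps / 2], [1.0])
        assert wasserstein(h0, h2) == pytest.approx(2.0, abs=1e-6)

    def test_uniform_vs_point_mass(self):
        # closed form: integral of (2t-1)^2 over [0,1] is 1/3
        u = HistogramElement([0.0, 2.0], [1.0])
        p = HistogramElement([1 - 5e-10, 1 + 5e-10], [1.0])
        assert wasserstein(u, p) == pytest.approx(1 / np.sqrt(3), abs=1e-6)

    def test_matches_quantile_quadrature(self, rng):
        for _ in range(25):
            h1, h2 = random_histogram(rng), random_histogram(rng)
            assert wasserstein(h1, h2) == pytest.approx(
                wasserstein_quadrature(h1, h2), abs=2e-6
            )

    def test_translation_equivariance(self, rng):
        h1, h2 = random_histogram(rng), random_histogram(rng)
        c = 3.7
        s1 = HistogramElement(h1.bin_edges + c, h1.masses)
        s2 = HistogramElement(h2.bin_edges + c, h2.masses)
        # shifting both leaves the distance unchanged
        assert wasserstein(s1, s2) == pytest.approx(wasserstein(h1, h2), abs=1e-10)
        # shifting one copy of the same shape gives |c|
        assert wasserstein(h1, s1) == pytest.approx(abs(c), abs=1e-10)


# --- margin and element matrices --------------------------------------------


def margin_brute(data, axis):
    n_i, n_k = data.shape
    if axis == "row":
        out = np.zeros((n_i, n_i))
        for i in range(n_i):
            for j in range(n_i):
                out[i, j] = sum(
                    element_sq_distance(data.elements[i, k], data.elements[j, k], data.kind)
                    for k in range(n_k)
                )
        return out
    out = np.zeros((n_k, n_k))
    for k in range(n_k):
        for l in range(n_k):
            out[k, l] = sum(
                element_sq_distance(data.elements[i, k], data.elements[i, l], data.kind)
                for i in range(n_i)
            )
    return out


class TestMarginMatrices:
    def test_scalar_hand_example_rows(self):
        data = MatrixFramedData.from_values(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert row_distance_matrix(data).D2[0, 1] == pytest.approx(25.0)

    def test_scalar_hand_example_cols(self):
        data = MatrixFramedData.from_values(np.array([[0.0, 3.0], [0.0, 4.0]]))
        assert col_distance_matrix(data).D2[0, 1] == pytest.approx(25.0)

    def test_identical_rows_zero_distance(self):
        data = MatrixFramedData.from_values(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 9.0]]))
        assert row_distance_matrix(data).D2[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kind_fixture", [
        "small_scalar_data", "small_series_data", "small_histogram_data",
    ])
    def test_matches_brute_force_all_kinds(self, kind_fixture, request):
        data, _ = request.getfixturevalue(kind_fixture)
        np.testing.assert_allclose(
            row_distance_matrix(data).D2, margin_brute(data, "row"), atol=1e-10
        )
        np.testing.assert_allclose(
            col_distance_matrix(data).D2, margin_brute(data, "column"), atol=1e-10
        )

    def test_column_matrix_is_row_matrix_of_transpose(self, small_scalar_data):
        data, _ = small_scalar_data
        np.testing.assert_allclose(
            col_distance_matrix(data).D2,
            row_distance_matrix(data.transpose()).D2,
            atol=1e-12,
        )


class TestElementMatrix:
    def test_scalar_pairwise_absolute_differences(self):
        data = MatrixFramedData.from_values(np.array([[0.0, 1.0], [3.0, 7.0]]))
        D = element_distance_matrix(data).D
        flat = [0.0, 1.0, 3.0, 7.0]
        for a in range(4):
            for b in range(4):
                assert D[a, b] == pytest.approx(abs(flat[a] - flat[b]))

    def test_matches_quadruple_loop_oracle(self, small_histogram_data):
        data, _ = small_histogram_data
        D = element_distance_matrix(data).D
        n_i, n_k = data.shape
        for a in range(n_i * n_k):
            for b in range(n_i * n_k):
                i, k = divmod(a, n_k)
                j, l = divmod(b, n_k)
                expected = np.sqrt(
                    element_sq_distance(data.elements[i, k], data.elements[j, l], data.kind)
                )
                assert D[a, b] == pytest.approx(expected, abs=1e-10)
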