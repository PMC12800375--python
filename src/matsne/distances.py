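"""Element-level and margin-level distances for matrix-framed data.

Three element kinds map to three metrics:

* scalars — absolute difference (Euclidean in 1-D);
* multivariate time series — per-coordinate dynamic time warping (DTW), each
  coordinate warped independently, squared and summed over coordinates;
* histograms — the L2-Wasserstein distance between piecewise-uniform
  densities, computed in closed form from the piecewise-linear quantile
  functions.

Row (column) margin distances square-sum the element distances across the
other axis; the affinity layer consumes these *squared* matrices.  The
unstructured all-pairs element distance matrix (unsquared, classical t-SNE
convention) feeds the classical baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit
from scipy.spatial.distance import squareform, pdist

from .data import HistogramElement, MatrixFramedData, SeriesElement

__all__ = [
    "MarginDistanceMatrix",
    "ElementDistanceMatrix",
    "dtw",
    "series_sq_distance",
    "wasserstein",
    "element_sq_distance",
    "row_distance_matrix",
    "col_distance_matrix",
    "element_distance_matrix",
]

StepPattern = Literal["symmetric1", "symmetric2"]


@dataclass
class MarginDistanceMatrix:
    """Symmetric matrix of *squared* distances over rows or over columns."""

    axis: Literal["row", "column"]
    D2: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        D2 = np.asarray(self.D2, dtype=float)
        if D2.ndim != 2 or D2.shape[0] != D2.shape[1]:
            raise ValueError("margin distance matrix must be square")
        if np.any(np.abs(np.diag(D2)) > 1e-12):
            raise ValueError("margin distance matrix must have zero diagonal")
        if np.max(np.abs(D2 - D2.T)) > 1e-12:
            raise ValueError("margin distance matrix must be symmetric")
        if np.any(D2 < -1e-12):
            raise ValueError("squared distances must be nonnegative")
        self.D2 = np.clip(D2, 0.0, None)

    @property
    def n(self) -> int:
        return self.D2.shape[0]


@dataclass
class ElementDistanceMatrix:
    """Symmetric (I·K)×(I·K) matrix of unsquared element-pair distances.

    Index order is row-major over (i, k).
    """

    D: np.ndarray
    shape_ik: tuple[int, int]

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = self.shape_ik[0] * self.shape_ik[1]
        if D.shape != (n, n):
            raise ValueError(f"expected {n}×{n} element distance matrix, got {D.shape}")
        if np.max(np.abs(D - D.T)) > 1e-12 or np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("element distance matrix must be symmetric, zero diagonal")
        self.D = np.clip(D, 0.0, None)


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------


@njit(cache=False)
def _dtw_cost(a: np.ndarray, b: np.ndarray, diag_weight: float) -> float:
    n, m = a.shape[0], b.shape[0]
    big = np.inf
    g = np.empty((n + 1, m + 1))
    g[:, :] = big
    g[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = abs(ai - b[j - 1])
            best = g[i - 1, j - 1] + diag_weight * d
            alt = g[i - 1, j] + d
            if alt < best:
                best = alt
            alt = g[i, j - 1] + d
            if alt < best:
                best = alt
            g[i, j] = best
    # first cell always costs d(1,1) with weight 1, whichever pattern
    return g[n, m] - (diag_weight - 1.0) * abs(a[0] - b[0])


def dtw(a, b, step: StepPattern = "symmetric2") -> float:
    """Unnormalized DTW cost between two 1-D sequences.

    Local cost is the absolute difference; the full alignment lattice is
    searched (no window).  ``symmetric2`` weights the diagonal step by 2 (the
    common R-package default), ``symmetric1`` weights all steps by 1.  The
    origin cell contributes ``|a[0]-b[0]|`` once under both patterns.
    """
    a = np.ascontiguousarray(a, dtype=float).ravel()
    b = np.ascontiguousarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw requires nonempty sequences")
    if step == "symmetric2":
        w = 2.0
    elif step == "symmetric1":
        w = 1.0
    else:
        raise ValueError(f"unknown step pattern {step!r}")
    return float(_dtw_cost(a, b, w))


def series_sq_distance(
    x: SeriesElement, y: SeriesElement, step: StepPattern = "symmetric2"
) -> float:
    """Sum over coordinates of squared per-coordinate DTW costs."""
    if x.n_dims != y.n_dims:
        raise ValueError(f"series dimensionality mismatch: {x.n_dims} vs {y.n_dims}")
    total = 0.0
    for p in range(x.n_dims):
        c = dtw(x.values[:, p], y.values[:, p], step=step)
        total += c * c
    return total


# ---------------------------------------------------------------------------
# L2-Wasserstein between histograms
# ---------------------------------------------------------------------------


def _quantile_breaks(h: HistogramElement) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-mass breakpoints and corresponding edge values."""
    cum = np.concatenate(([0.0], np.cumsum(h.masses)))
    cum[-1] = 1.0
    return cum, h.bin_edges


def _eval_quantile(cum: np.ndarray, edges: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.interp(t, cum, edges)


def wasserstein(h1: HistogramElement, h2: HistogramElement) -> float:
    """L2-Wasserstein distance between two histograms.

    With uniform density inside each bin the quantile function Q is piecewise
    linear in the cumulative mass t, so on the merged grid of both histograms'
    cumulative breakpoints the difference Q1−Q2 is linear on every
    subinterval and ∫(Q1−Q2)² dt has the exact closed form
    h/3·(d0² + d0·d1 + d1²).  Endpoint values are reconstructed from interior
    evaluations so that zero-mass bins (quantile jumps at breakpoints, a
    measure-zero set) cannot contaminate the integral.
    """
    c1, e1 = _quantile_breaks(h1)
    c2, e2 = _quantile_breaks(h2)
    grid = np.unique(np.concatenate((c1, c2)))
    t0 = grid[:-1]
    t1 = grid[1:]
    h = t1 - t0
    keep = h > 0
    t0, t1, h = t0[keep], t1[keep], h[keep]
    q1 = t0 + 0.25 * h
    qm = t0 + 0.50 * h
    q3 = t0 + 0.75 * h

    def diff(t: np.ndarray) -> np.ndarray:
        return _eval_quantile(c1, e1, t) - _eval_quantile(c2, e2, t)

    d_m = diff(qm)
    d_0 = 2.0 * diff(q1) - d_m
    d_1 = 2.0 * diff(q3) - d_m
    integral = np.sum(h / 3.0 * (d_0 * d_0 + d_0 * d_1 + d_1 * d_1))
    return float(np.sqrt(max(integral, 0.0)))


# ---------------------------------------------------------------------------
# element-level dispatch and margin matrices
# ---------------------------------------------------------------------------


def element_sq_distance(x, y, kind: str, step: StepPattern = "symmetric2") -> float:
    """Squared distance between two elements of the given kind."""
    if kind == "scalar":
        d = x.value - y.value
        return d * d
    if kind == "series":
        return series_sq_distance(x, y, step=step)
    if kind == "histogram":
        w = wasserstein(x, y)
        return w * w
    raise ValueError(f"unknown element kind {kind!r}")


def row_distance_matrix(
    data: MatrixFramedData, step: StepPattern = "symmetric2"
) -> MarginDistanceMatrix:
    """Squared row-margin distances: D2[i,j] = Σ_k d(X_ik, X_jk)²."""
    if data.kind == "scalar":
        V = data.values()
        D2 = squareform(pdist(V, metric="sqeuclidean"))
        return MarginDistanceMatrix("row", D2, list(data.row_ids))
    n_i, n_k = data.shape
    D2 = np.zeros((n_i, n_i))
    for i in range(n_i):
        for j in range(i + 1, n_i):
            total = 0.0
            for k in range(n_k):
                total += element_sq_distance(
                    data.elements[i, k], data.elements[j, k], data.kind, step=step
                )
            D2[i, j] = D2[j, i] = total
    return MarginDistanceMatrix("row", D2, list(data.row_ids))


def col_distance_matrix(
    data: MatrixFramedData, step: StepPattern = "symmetric2"
) -> MarginDistanceMatrix:
    """Squared column-margin distances: D2[k,l] = Σ_i d(X_ik, X_il)²."""
    out = row_distance_matrix(data.transpose(), step=step)
    return MarginDistanceMatrix("column", out.D2, list(data.col_ids))


def element_distance_matrix(
    data: MatrixFramedData, step: StepPattern = "symmetric2"
) -> ElementDistanceMatrix:
    """All-pairs unsquared distances over the I·K flattened elements."""
    n_i, n_k = data.shape
    if data.kind == "scalar":
        v = data.values().reshape(-1, 1)
        D = np.abs(v - v.T)
        return ElementDistanceMatrix(D, (n_i, n_k))
    flat = [data.elements[i, k] for i in range(n_i) for k in range(n_k)]
    n = len(flat)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d2 = element_sq_distance(flat[a], flat[b], data.kind, step=step)
            D[a, b] = D[b, a] = np.sqrt(d2)
    return ElementDistanceMatrix(D, (n_i, n_k))
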