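"""High- and low-dimensional affinities with perplexity-calibrated bandwidths.

The high-dimensional side follows the classical t-SNE construction applied to
a margin (row or column) squared-distance matrix: a Gaussian conditional
distribution per point whose bandwidth σ_i is found by bisection so that its
perplexity 2^H equals a target, then symmetrized into a joint distribution
P[i,j] = (p_{j|i} + p_{i|j}) / (2n).  Rows and columns get independently
calibrated perplexities, which is what makes the method insensitive to scale
differences between the two margins.

The low-dimensional side is the Student-t (one degree of freedom) kernel on
*aggregated* embedding distances: for the row axis the squared distance
between rows i and j is Σ_k ‖Y_ik − Y_jk‖², and symmetrically for columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data import Embedding, MatrixFramedData
from .distances import MarginDistanceMatrix, col_distance_matrix, row_distance_matrix

__all__ = [
    "AffinityMatrix",
    "LowDimAffinity",
    "conditional_row",
    "calibrate_bandwidth",
    "conditional_matrix",
    "symmetrize",
    "lowdim_affinity",
    "build_affinities",
    "aggregated_sq_distances",
]

_SIGMA_LO = 1e-10
_SIGMA_HI = 1e10


@dataclass
class AffinityMatrix:
    """Symmetrized joint probabilities over one margin, with the σ used per point."""

    P: np.ndarray
    sigmas: np.ndarray
    perplexity: float
    axis: Literal["row", "column"]
    #: indices whose bandwidth search hit the bracket boundary
    uncalibrated: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError(f"affinity mass is {P.sum()!r}, expected 1")
        if np.max(np.abs(np.diag(P))) > 0:
            raise ValueError("affinity diagonal must be zero")
        if np.max(np.abs(P - P.T)) > 1e-12:
            raise ValueError("affinity matrix must be symmetric")
        self.P = P

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class LowDimAffinity:
    """Student-t joint probabilities over one margin of an embedding."""

    Q: np.ndarray
    axis: Literal["row", "column"]

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if abs(Q.sum() - 1.0) > 1e-9:
            raise ValueError(f"low-dim affinity mass is {Q.sum()!r}, expected 1")
        self.Q = Q


def conditional_row(
    D2: MarginDistanceMatrix | np.ndarray,
    i: int,
    sigma: float,
    pair_normalized: bool = False,
) -> np.ndarray:
    """Gaussian conditional distribution p_{·|i} at bandwidth ``sigma``.

    ``pair_normalized=True`` normalizes by a sum over all ordered pairs
    instead; the default normalizes over j ≠ i for the fixed i, which is the
    classical conditional and the form consistent with a per-point perplexity.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    D2 = D2.D2 if isinstance(D2, MarginDistanceMatrix) else np.asarray(D2, dtype=float)
    n = D2.shape[0]
    row = D2[i] / (2.0 * sigma * sigma)
    mask = np.arange(n) != i
    # log-sum-exp guard: shift by the off-diagonal minimum before exponentiating
    shifted = row[mask] - row[mask].min()
    w = np.exp(-shifted)
    p = np.zeros(n)
    if pair_normalized:
        # literal variant: weights for every ordered pair at this σ share one Z
        W = np.exp(-(D2 / (2.0 * sigma * sigma) - row[mask].min()))
        np.fill_diagonal(W, 0.0)
        p[mask] = w / W.sum()
    else:
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(f"degenerate conditional distribution at point {i}")
        p[mask] = w / total
    return p


def _perplexity_of(p: np.ndarray) -> float:
    """2^H of a probability vector (zeros contribute nothing)."""
    pos = p[p > 0]
    h_bits = -np.sum(pos * np.log2(pos))
    return float(2.0**h_bits)


def calibrate_bandwidth(
    D2_row: np.ndarray,
    i: int,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[float, bool]:
    """Bisection on log σ so that p_{·|i} hits the target perplexity.

    The entropy of the conditional is monotone nondecreasing in σ, so plain
    bisection on log σ over [1e-10, 1e10] converges.  Returns ``(sigma,
    converged)``; when the target is unattainable inside the bracket the
    boundary σ is returned with ``converged=False`` so callers can log it.
    """
    D2_row = np.asarray(D2_row, dtype=float)
    n = D2_row.shape[0]
    if not 1.0 < perplexity <= n - 1:
        raise ValueError(
            f"perplexity must lie in (1, n-1] = (1, {n - 1}], got {perplexity}"
        )

    def achieved(log_sigma: float) -> float:
        return _perplexity_of(_cond_from_row(D2_row, i, np.exp(log_sigma)))

    lo, hi = np.log(_SIGMA_LO), np.log(_SIGMA_HI)
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        perp = achieved(mid)
        if abs(perp - perplexity) < tol:
            return float(np.exp(mid)), True
        if perp > perplexity:
            hi = mid
        else:
            lo = mid
    sigma = float(np.exp(mid))
    return sigma, abs(achieved(mid) - perplexity) < tol


def _cond_from_row(D2_row: np.ndarray, i: int, sigma: float) -> np.ndarray:
    n = D2_row.shape[0]
    mask = np.arange(n) != i
    scaled = D2_row[mask] / (2.0 * sigma * sigma)
    w = np.exp(-(scaled - scaled.min()))
    p = np.zeros(n)
    p[mask] = w / w.sum()
    return p


def conditional_matrix(
    D2: MarginDistanceMatrix | np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Calibrate every point and stack the conditionals; rows sum to 1.

    Returns (Pcond, sigmas, uncalibrated_indices).
    """
    D2 = D2.D2 if isinstance(D2, MarginDistanceMatrix) else np.asarray(D2, dtype=float)
    n = D2.shape[0]
    Pcond = np.zeros((n, n))
    sigmas = np.empty(n)
    flagged: list[int] = []
    for i in range(n):
        sigma, ok = calibrate_bandwidth(D2[i], i, perplexity, tol=tol, max_iter=max_iter)
        if not ok:
            flagged.append(i)
        sigmas[i] = sigma
        Pcond[i] = _cond_from_row(D2[i], i, sigma)
    return Pcond, sigmas, flagged


def symmetrize(
    Pcond: np.ndarray,
    sigmas: np.ndarray | None = None,
    perplexity: float = float("nan"),
    axis: Literal["row", "column"] = "row",
    uncalibrated: list[int] | None = None,
) -> AffinityMatrix:
    """Joint affinities P[i,j] = (p_{j|i} + p_{i|j}) / (2n); total mass 1."""
    Pcond = np.asarray(Pcond, dtype=float)
    n = Pcond.shape[0]
    P = (Pcond + Pcond.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    if sigmas is None:
        sigmas = np.full(n, np.nan)
    return AffinityMatrix(
        P=P,
        sigmas=np.asarray(sigmas, dtype=float),
        perplexity=perplexity,
        axis=axis,
        uncalibrated=list(uncalibrated or []),
    )


def affinities_from_margin(
    D2: MarginDistanceMatrix,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> AffinityMatrix:
    """Calibrated, symmetrized joint affinities from one margin distance matrix."""
    Pcond, sigmas, flagged = conditional_matrix(D2, perplexity, tol=tol, max_iter=max_iter)
    return symmetrize(Pcond, sigmas, perplexity, axis=D2.axis, uncalibrated=flagged)


def build_affinities(
    data: MatrixFramedData,
    perp_r: float,
    perp_c: float,
    step: str = "symmetric2",
) -> tuple[AffinityMatrix, AffinityMatrix]:
    """Row and column joint affinities for a dataset, each with its own perplexity."""
    Dr = row_distance_matrix(data, step=step)
    Dc = col_distance_matrix(data, step=step)
    return (
        affinities_from_margin(Dr, perp_r),
        affinities_from_margin(Dc, perp_c),
    )


# ---------------------------------------------------------------------------
# low-dimensional (Student-t) affinities
# ---------------------------------------------------------------------------


def aggregated_sq_distances(Y: np.ndarray, axis: Literal["row", "column"]) -> np.ndarray:
    """Margin-aggregated squared embedding distances.

    For the row axis: S[i,j] = Σ_k ‖Y_ik − Y_jk‖²; column axis swaps roles.
    ``Y`` has shape (I, K, 2).
    """
    if axis == "column":
        Y = np.swapaxes(Y, 0, 1)
    # ||Yik - Yjk||^2 summed over k, via the Gram expansion per slice k
    sq = np.sum(Y * Y, axis=2)  # (I, K)
    cross = np.einsum("ikc,jkc->ij", Y, Y)  # Σ_k <Yik, Yjk>
    S = sq.sum(axis=1)[:, None] + sq.sum(axis=1)[None, :] - 2.0 * cross
    np.fill_diagonal(S, 0.0)
    return np.clip(S, 0.0, None)


def lowdim_affinity(Y: Embedding | np.ndarray, axis: Literal["row", "column"]) -> LowDimAffinity:
    """Student-t joint probabilities over one margin of the embedding."""
    Y = Y.Y if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("embedding contains non-finite coordinates")
    S = aggregated_sq_distances(Y, axis)
    W = 1.0 / (1.0 + S)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    return LowDimAffinity(Q=Q, axis=axis)
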