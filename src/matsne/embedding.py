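"""Matrix t-SNE objective, gradient, and momentum optimizer.

The method embeds every (row, column) element of a matrix-framed dataset as a
2-D point Y_ik while minimizing a convex combination of two KL divergences:

    C(Y) = α · KL(P^r ‖ Q^r) + (1 − α) · KL(P^c ‖ Q^c),

where P^r, P^c are perplexity-calibrated joint affinities over the row and
column margins of the data, and Q^r, Q^c are Student-t affinities over the
*aggregated* embedding distances Σ_k ‖Y_ik − Y_jk‖² (rows) and
Σ_i ‖Y_ik − Y_il‖² (columns).  Neither KL term separates over elements, so
the optimizer couples every element to its whole row and whole column.

The boundary weights α = 0 and α = 1 correspond to the original t-SNE on a
single margin; ``matrix_tsne`` dispatches those cases to the classical engine
on the margin distance matrix and broadcasts the margin points across the
collapsed axis (with the aggregated Student-t kernel of the interior
objective, a collapsed axis would rescale squared distances by the number of
collapsed copies, which is not the classical kernel — the boundary cases are
classical t-SNE by definition, so they are run as such).

Optimization is gradient descent with momentum: γ = 0.5 for the first 250
iterations and 0.8 after, learning rate η = 100, M = 1000 iterations by
default, with the two standard stabilizers of that recipe — per-parameter
adaptive gains and 4× early exaggeration for the first 50 iterations — on by
default and exposed as flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np

from .affinities import (
    AffinityMatrix,
    build_affinities,
    conditional_matrix,
    symmetrize,
)
from .data import Embedding, MatrixFramedData
from .distances import (
    ElementDistanceMatrix,
    MarginDistanceMatrix,
    col_distance_matrix,
    row_distance_matrix,
)

__all__ = [
    "OptimizerConfig",
    "RunTrace",
    "kl_cost",
    "gradient",
    "matrix_tsne",
    "classical_tsne",
    "convex_distance_tsne",
    "default_perplexity",
]

GradientVariant = Literal["cost_consistent", "as_printed"]


def default_perplexity(n: int, cap: float = 30.0) -> float:
    """min(n/3, 30), clamped into the feasible band (1, n−1]."""
    perp = min(n / 3.0, cap)
    return float(min(max(perp, 1.0 + 1e-9), n - 1))


@dataclass
class OptimizerConfig:
    """Knobs of the momentum gradient-descent optimizer."""

    alpha: float = 0.5
    iterations: int = 1000
    eta: float = 100.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch: int = 250
    perp_r: float | None = None
    perp_c: float | None = None
    seed: int = 0
    early_exaggeration_factor: float = 4.0
    early_exaggeration_iters: int = 50
    gradient_variant: GradientVariant = "cost_consistent"
    center_each_iter: bool = True
    init_scale: float = 1e-4
    use_gains: bool = True
    record_trajectory: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class RunTrace:
    """Per-iteration cost values plus run metadata."""

    costs: list[float]
    seed: int
    config: dict
    trajectory: list[np.ndarray] | None = None

    @property
    def final_cost(self) -> float:
        return self.costs[-1]

    def to_dict(self) -> dict:
        return {"costs": self.costs, "final_cost": self.final_cost, "seed": self.seed,
                "config": {k: v for k, v in self.config.items()}}


# ---------------------------------------------------------------------------
# cost and gradient
# ---------------------------------------------------------------------------


def _margin_kernel(Y: np.ndarray, axis: Literal["row", "column"], counter: list | None = None):
    """Aggregated squared distances, Student-t weights and normalized Q for one axis."""
    Z = np.swapaxes(Y, 0, 1) if axis == "column" else Y
    n, m, _ = Z.shape
    sq = np.sum(Z * Z, axis=2)
    cross = np.einsum("ikc,jkc->ij", Z, Z)
    S = sq.sum(axis=1)[:, None] + sq.sum(axis=1)[None, :] - 2.0 * cross
    np.fill_diagonal(S, 0.0)
    np.clip(S, 0.0, None, out=S)
    W = 1.0 / (1.0 + S)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    if counter is not None:
        # multiply-add tally of the dense tensor contractions above
        counter[0] += 2 * n * n * m * 2  # cross einsum (mults + adds)
        counter[0] += 4 * n * n  # S assembly, clip, W, Q
    return W, Q


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    q = np.where(Q > 0, Q, 1.0)
    return float(np.sum(P[mask] * np.log(P[mask] / q[mask])))


def kl_cost(
    Pr: AffinityMatrix | np.ndarray,
    Pc: AffinityMatrix | np.ndarray,
    Y: Embedding | np.ndarray,
    alpha: float,
) -> float:
    """C = α·KL(P^r‖Q^r) + (1−α)·KL(P^c‖Q^c), diagonal excluded, 0·log0 = 0."""
    Pr = Pr.P if isinstance(Pr, AffinityMatrix) else np.asarray(Pr, dtype=float)
    Pc = Pc.P if isinstance(Pc, AffinityMatrix) else np.asarray(Pc, dtype=float)
    Y = Y.Y if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    cost = 0.0
    if alpha > 0:
        _, Qr = _margin_kernel(Y, "row")
        cost += alpha * _kl(Pr, Qr)
    if alpha < 1:
        _, Qc = _margin_kernel(Y, "column")
        cost += (1.0 - alpha) * _kl(Pc, Qc)
    return cost


def gradient(
    Pr: AffinityMatrix | np.ndarray,
    Pc: AffinityMatrix | np.ndarray,
    Y: Embedding | np.ndarray,
    alpha: float,
    variant: GradientVariant = "cost_consistent",
    count_ops: bool = False,
):
    """Gradient of the combined cost w.r.t. every Y_ik.

    ``cost_consistent`` uses leading factors 4α and 4(1−α), the analytic
    gradient of the convex-combination cost; ``as_printed`` uses 4α² and
    4(1−α)².  Both share the attraction–repulsion structure
    (p − q)·(1 + aggregated distance²)⁻¹·(coordinate difference).

    With ``count_ops=True`` also returns a tally of elementary multiply-adds
    performed by the dense tensor operations, which scales as Θ(IK(I+K)).
    """
    Pr = Pr.P if isinstance(Pr, AffinityMatrix) else np.asarray(Pr, dtype=float)
    Pc = Pc.P if isinstance(Pc, AffinityMatrix) else np.asarray(Pc, dtype=float)
    Y = Y.Y if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    n_i, n_k, _ = Y.shape
    counter = [0] if count_ops else None

    if variant == "cost_consistent":
        f_r, f_c = 4.0 * alpha, 4.0 * (1.0 - alpha)
    elif variant == "as_printed":
        f_r, f_c = 4.0 * alpha**2, 4.0 * (1.0 - alpha) ** 2
    else:
        raise ValueError(f"unknown gradient variant {variant!r}")

    grad = np.zeros_like(Y)
    if f_r != 0.0:
        Wr, Qr = _margin_kernel(Y, "row", counter)
        Ar = (Pr - Qr) * Wr  # (I, I)
        rs = Ar.sum(axis=1)
        grad += f_r * (rs[:, None, None] * Y - np.einsum("ij,jkc->ikc", Ar, Y))
        if counter is not None:
            counter[0] += 2 * n_i * n_i * n_k * 2  # row einsum contraction
            counter[0] += 3 * n_i * n_i + 2 * n_i * n_k * 2
    if f_c != 0.0:
        Wc, Qc = _margin_kernel(Y, "column", counter)
        Ac = (Pc - Qc) * Wc  # (K, K)
        cs = Ac.sum(axis=1)
        grad += f_c * (cs[None, :, None] * Y - np.einsum("kl,ilc->ikc", Ac, Y))
        if counter is not None:
            counter[0] += 2 * n_k * n_k * n_i * 2
            counter[0] += 3 * n_k * n_k + 2 * n_i * n_k * 2
    if count_ops:
        return grad, counter[0]
    return grad


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


def _momentum(config: OptimizerConfig, m: int) -> float:
    return config.momentum_early if m < config.momentum_switch else config.momentum_late


def _classical_engine(
    P: np.ndarray, config: OptimizerConfig, n: int
) -> tuple[np.ndarray, RunTrace]:
    """Classical t-SNE loop on n points given a joint affinity matrix P."""
    rng = np.random.default_rng(config.seed)
    y = rng.standard_normal((n, 2)) * config.init_scale
    prev = y.copy()
    gains = np.ones_like(y)
    update = np.zeros_like(y)
    costs: list[float] = []
    traj: list[np.ndarray] | None = [] if config.record_trajectory else None
    for m in range(config.iterations + 1):
        P_eff = P
        if m < config.early_exaggeration_iters:
            P_eff = P * config.early_exaggeration_factor
        sq = np.sum(y * y, axis=1)
        S = sq[:, None] + sq[None, :] - 2.0 * (y @ y.T)
        np.fill_diagonal(S, 0.0)
        np.clip(S, 0.0, None, out=S)
        W = 1.0 / (1.0 + S)
        np.fill_diagonal(W, 0.0)
        Q = W / W.sum()
        costs.append(_kl(P, Q))
        if traj is not None:
            traj.append(y.copy())
        if m == config.iterations:
            break
        A = (P_eff - Q) * W
        rs = A.sum(axis=1)
        grad = 4.0 * (rs[:, None] * y - A @ y)
        step = y - prev
        if config.use_gains:
            same_sign = np.sign(grad) == np.sign(step)
            gains = np.where(same_sign, gains * 0.8, gains + 0.2)
            gains = np.clip(gains, 0.01, None)
            update = -config.eta * gains * grad + _momentum(config, m) * step
        else:
            update = -config.eta * grad + _momentum(config, m) * step
        y_new = y + update
        if not np.all(np.isfinite(y_new)):
            raise FloatingPointError(f"optimization diverged at iteration {m}")
        if config.center_each_iter:
            y_new = y_new - y_new.mean(axis=0)
        prev, y = y, y_new
    trace = RunTrace(costs=costs, seed=config.seed, config=asdict(config), trajectory=traj)
    return y, trace


def _resolve_affinities(
    data_or_affinities, config: OptimizerConfig
) -> tuple[AffinityMatrix, AffinityMatrix, list[str], list[str]]:
    if isinstance(data_or_affinities, MatrixFramedData):
        data = data_or_affinities
        perp_r = config.perp_r if config.perp_r is not None else default_perplexity(data.n_rows)
        perp_c = config.perp_c if config.perp_c is not None else default_perplexity(data.n_cols)
        Pr, Pc = build_affinities(data, perp_r, perp_c)
        return Pr, Pc, list(data.row_ids), list(data.col_ids)
    Pr, Pc = data_or_affinities
    row_ids = [f"r{i}" for i in range(Pr.n)]
    col_ids = [f"c{k}" for k in range(Pc.n)]
    return Pr, Pc, row_ids, col_ids


def matrix_tsne(
    data_or_affinities, config: OptimizerConfig
) -> tuple[Embedding, RunTrace]:
    """Embed all I·K elements by minimizing the convex-combination KL cost.

    Accepts either a :class:`MatrixFramedData` (margins and affinities are
    computed with ``config.perp_r``/``perp_c``, defaulting to min(n/3, 30)
    per margin) or a precomputed ``(row AffinityMatrix, column
    AffinityMatrix)`` pair.  α = 1 and α = 0 run the classical engine on the
    row / column margin and broadcast; interior α runs the coupled loop from
    a small Gaussian initialization.  Deterministic given ``config.seed``.
    """
    Pr, Pc, row_ids, col_ids = _resolve_affinities(data_or_affinities, config)
    n_i, n_k = Pr.n, Pc.n

    if config.alpha in (0.0, 1.0):
        P = Pr.P if config.alpha == 1.0 else Pc.P
        n = n_i if config.alpha == 1.0 else n_k
        y, trace = _classical_engine(P, config, n)
        if config.alpha == 1.0:
            Y = np.repeat(y[:, None, :], n_k, axis=1)
        else:
            Y = np.repeat(y[None, :, :], n_i, axis=0)
        return Embedding(row_ids=row_ids, col_ids=col_ids, Y=Y), trace

    rng = np.random.default_rng(config.seed)
    Y = rng.standard_normal((n_i, n_k, 2)) * config.init_scale
    prev = Y.copy()
    gains = np.ones_like(Y)
    costs: list[float] = []
    traj: list[np.ndarray] | None = [] if config.record_trajectory else None
    for m in range(config.iterations + 1):
        exaggerate = m < config.early_exaggeration_iters
        Pr_eff = Pr.P * config.early_exaggeration_factor if exaggerate else Pr.P
        Pc_eff = Pc.P * config.early_exaggeration_factor if exaggerate else Pc.P
        costs.append(kl_cost(Pr.P, Pc.P, Y, config.alpha))
        if traj is not None:
            traj.append(Y.copy())
        if m == config.iterations:
            break
        grad = gradient(Pr_eff, Pc_eff, Y, config.alpha, variant=config.gradient_variant)
        step = Y - prev
        if config.use_gains:
            same_sign = np.sign(grad) == np.sign(step)
            gains = np.where(same_sign, gains * 0.8, gains + 0.2)
            gains = np.clip(gains, 0.01, None)
            update = -config.eta * gains * grad + _momentum(config, m) * step
        else:
            update = -config.eta * grad + _momentum(config, m) * step
        Y_new = Y + update
        if not np.all(np.isfinite(Y_new)):
            raise FloatingPointError(f"optimization diverged at iteration {m}")
        if config.center_each_iter:
            Y_new = Y_new - Y_new.reshape(-1, 2).mean(axis=0)
        prev, Y = Y, Y_new
    trace = RunTrace(costs=costs, seed=config.seed, config=asdict(config), trajectory=traj)
    return Embedding(row_ids=row_ids, col_ids=col_ids, Y=Y), trace


def classical_tsne(
    D: ElementDistanceMatrix | MarginDistanceMatrix | np.ndarray,
    perplexity: float,
    config: OptimizerConfig,
) -> tuple[np.ndarray, RunTrace]:
    """Standard t-SNE on an unsquared distance matrix (or a squared margin one).

    Conditional Gaussian affinities are calibrated on the squared distances,
    symmetrized over the n points, and optimized against the pairwise
    Student-t kernel with the same momentum loop used everywhere else.  This
    is the unstructured-distance baseline when fed the all-pairs element
    distance matrix, and the margin engine behind α ∈ {0, 1}.
    """
    if isinstance(D, ElementDistanceMatrix):
        D2 = D.D ** 2
    elif isinstance(D, MarginDistanceMatrix):
        D2 = D.D2
    else:
        D = np.asarray(D, dtype=float)
        D2 = D ** 2
    n = D2.shape[0]
    if not 1.0 < perplexity <= n - 1:
        raise ValueError(f"perplexity must lie in (1, {n - 1}], got {perplexity}")
    Pcond, sigmas, flagged = conditional_matrix(D2, perplexity)
    P = symmetrize(Pcond, sigmas, perplexity, axis="row", uncalibrated=flagged)
    return _classical_engine(P.P, config, n)


def convex_distance_tsne(
    data: MatrixFramedData,
    alpha: float,
    config: OptimizerConfig,
    perplexity: float | None = None,
    step: str = "symmetric2",
) -> tuple[np.ndarray, RunTrace]:
    """Baseline: classical t-SNE on a convex combination of margin distances.

    Element pair ((i,k),(j,l)) gets squared distance
    α·d_r(i,j)² + (1−α)·d_c(k,l)², then a single classical t-SNE runs on the
    I·K points.  Simpler than the convex-combination *cost*, but sensitive to
    scale differences between the margins (one shared perplexity).
    """
    Dr = row_distance_matrix(data, step=step).D2
    Dc = col_distance_matrix(data, step=step).D2
    n_i, n_k = data.shape
    # δ²[(i,k),(j,l)] in row-major flattening
    delta2 = alpha * np.kron(Dr, np.ones((n_k, n_k))) + (1.0 - alpha) * np.kron(
        np.ones((n_i, n_i)), Dc
    )
    n = n_i * n_k
    if perplexity is None:
        perplexity = default_perplexity(n)
    return classical_tsne(np.sqrt(delta2), perplexity, config)
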