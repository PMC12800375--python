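"""Selection of the convex weight α and cluster-separability evaluation.

The weight α trades off how strongly the embedding preserves row-wise versus
column-wise group structure.  Selection proceeds in three steps:

1. Run the boundary embeddings α = 1 (rows) and α = 0 (columns).  On each
   margin's distinct points, find the number of clusters as the smallest g
   whose K-means partition exceeds a separability threshold:
   G = min{g : SSB(g)/SST(g) > 0.9}, where SSB is the between-cluster and
   SST the total sum of squares.  When group memberships are known a priori,
   the K-means step is skipped and the known counts/labels are used.
2. Form cross-product ground-truth labels: element (i, k) is labeled by the
   pair (row cluster of i, column cluster of k), giving G = G0·G1 classes.
3. For each candidate α on a grid in (0, 1), run the full embedding and
   score the I·K points — by SSB/SST over the cross-product labels, or by
   ARI/NMI of a fresh K-means(G) against them.  α* is the argmax (ties →
   smallest α).

A seed-perturbation evaluation re-runs the embedding under several random
initializations and tabulates ARI/NMI/SSB-SST per seed, optionally alongside
the unstructured classical baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .data import Embedding, MatrixFramedData
from .distances import element_distance_matrix
from .embedding import OptimizerConfig, classical_tsne, matrix_tsne

__all__ = [
    "WeightSelectionReport",
    "ssb_sst_ratio",
    "kmeans_labels",
    "select_marginal_G",
    "cross_product_labels",
    "select_alpha",
    "seed_perturbation_eval",
    "margin_points",
]

Metric = Literal["ssb_sst", "ari", "nmi"]

DEFAULT_ALPHA_GRID = np.round(np.arange(0.02, 0.99, 0.02), 2)


@dataclass
class WeightSelectionReport:
    """Everything the α-selection procedure computed."""

    G0: int
    G1: int
    G: int
    alphas: np.ndarray
    score_per_alpha: dict[float, float]
    alpha_star: float
    metric: Metric
    row_labels: np.ndarray
    col_labels: np.ndarray
    seed: int
    g0_flagged: bool = False
    g1_flagged: bool = False

    def __post_init__(self) -> None:
        if self.alpha_star not in set(float(a) for a in self.alphas):
            raise ValueError("alpha_star must be one of the candidate weights")
        best = max(self.score_per_alpha.values())
        if self.score_per_alpha[self.alpha_star] < best - 1e-12:
            raise ValueError("alpha_star must attain the maximum score")

    def to_dict(self) -> dict:
        return {
            "G0": self.G0,
            "G1": self.G1,
            "G": self.G,
            "metric": self.metric,
            "alpha_star": self.alpha_star,
            "alphas": [float(a) for a in self.alphas],
            "score_per_alpha": {f"{a:g}": s for a, s in self.score_per_alpha.items()},
            "row_labels": [int(x) for x in self.row_labels],
            "col_labels": [int(x) for x in self.col_labels],
            "seed": self.seed,
            "g0_flagged": self.g0_flagged,
            "g1_flagged": self.g1_flagged,
        }


def ssb_sst_ratio(points: np.ndarray, labels: Sequence[int]) -> float:
    """Between-cluster over total sum of squares, in [0, 1].

    SSB = Σ_g n_g‖mean_g − mean‖², SST = Σ‖x − mean‖².  Equals 0 when every
    cluster mean coincides with the grand mean and 1 when within-cluster
    scatter vanishes.  All-identical points (SST = 0) are an error.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need an n×d array with n >= 2")
    if labels.shape[0] != points.shape[0]:
        raise ValueError("labels length must match number of points")
    grand = points.mean(axis=0)
    sst = float(np.sum((points - grand) ** 2))
    if sst == 0.0:
        raise ValueError("SST is zero: all points identical")
    ssb = 0.0
    for lab in np.unique(labels):
        grp = points[labels == lab]
        ssb += grp.shape[0] * float(np.sum((grp.mean(axis=0) - grand) ** 2))
    return min(ssb / sst, 1.0)


def kmeans_labels(points: np.ndarray, g: int, restarts: int = 20, seed: int = 0) -> np.ndarray:
    """Best-of-restarts K-means assignment; deterministic given seed."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= g <= n:
        raise ValueError(f"cluster count g must lie in [1, {n}], got {g}")
    if g == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=g, n_init=restarts, random_state=seed)
    return km.fit_predict(points)


def select_marginal_G(
    points: np.ndarray,
    g_max: int | None = None,
    threshold: float = 0.9,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[int, bool]:
    """Smallest g whose K-means partition satisfies SSB/SST > threshold.

    ``points`` are the distinct margin points of a boundary (α ∈ {0, 1}) run.
    Returns (g, flagged); ``flagged`` is True when no g qualifies (g_max is
    returned) or the configuration is degenerate (SST = 0, returns 1).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if g_max is None:
        g_max = min(n - 1, 15)
    g_max = min(g_max, n)
    grand = points.mean(axis=0)
    if float(np.sum((points - grand) ** 2)) == 0.0:
        return 1, True
    for g in range(1, g_max + 1):
        labels = kmeans_labels(points, g, restarts=restarts, seed=seed)
        if g == 1:
            ratio = 0.0
        else:
            ratio = ssb_sst_ratio(points, labels)
        if ratio > threshold:
            return g, False
    return g_max, True


def margin_points(embedding: Embedding, alpha: float) -> np.ndarray:
    """Distinct margin points of a boundary embedding.

    At α = 1 every row's K copies coincide; the I shared points are taken
    (symmetrically the K column points at α = 0).
    """
    if alpha == 1.0:
        return embedding.Y[:, 0, :].copy()
    if alpha == 0.0:
        return embedding.Y[0, :, :].copy()
    raise ValueError("margin points are defined only for boundary runs (alpha 0 or 1)")


def cross_product_labels(
    row_labels: Sequence[int], col_labels: Sequence[int]
) -> np.ndarray:
    """Label element (i, k) by the pair (row_labels[i], col_labels[k]).

    Output is a single integer per element in row-major (i, k) order; the
    number of distinct labels is at most (#distinct rows)·(#distinct cols).
    """
    row_labels = np.asarray(row_labels)
    col_labels = np.asarray(col_labels)
    n_col_classes = len(np.unique(col_labels))
    col_codes = {lab: c for c, lab in enumerate(np.unique(col_labels))}
    row_codes = {lab: r for r, lab in enumerate(np.unique(row_labels))}
    out = np.empty(row_labels.size * col_labels.size, dtype=int)
    idx = 0
    for r in row_labels:
        for c in col_labels:
            out[idx] = row_codes[r] * n_col_classes + col_codes[c]
            idx += 1
    return out


def _score_embedding(
    points: np.ndarray,
    truth: np.ndarray,
    G: int,
    metric: Metric,
    seed: int,
    restarts: int = 20,
    fresh_kmeans_for_ssb: bool = False,
) -> float:
    if metric == "ssb_sst":
        labels = (
            kmeans_labels(points, G, restarts=restarts, seed=seed)
            if fresh_kmeans_for_ssb
            else truth
        )
        return ssb_sst_ratio(points, labels)
    pred = kmeans_labels(points, G, restarts=restarts, seed=seed)
    if metric == "ari":
        return adjusted_rand_score(truth, pred)
    if metric == "nmi":
        return normalized_mutual_info_score(truth, pred)
    raise ValueError(f"unknown metric {metric!r}")


def select_alpha(
    data: MatrixFramedData,
    config: OptimizerConfig,
    alpha_grid: Sequence[float] | None = None,
    metric: Metric = "ssb_sst",
    known_row_labels: Sequence[int] | None = None,
    known_col_labels: Sequence[int] | None = None,
    g_max: int | None = None,
    threshold: float = 0.9,
    restarts: int = 20,
    fresh_kmeans_for_ssb: bool = False,
) -> WeightSelectionReport:
    """Full α-selection procedure: marginal runs → G0, G1 → grid search → α*.

    When ``known_row_labels`` / ``known_col_labels`` are supplied the K-means
    identification of marginal clusters is skipped and the known groups
    define G1 / G0 directly.  Ties on the grid resolve to the smallest α.
    """
    alphas = np.asarray(
        DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid, dtype=float
    )
    if alphas.size == 0:
        raise ValueError("alpha grid is empty")
    if np.any((alphas <= 0) | (alphas >= 1)):
        raise ValueError("alpha grid must lie strictly inside (0, 1)")
    seed = config.seed
    g1_flag = g0_flag = False

    # --- marginal structure -------------------------------------------------
    if known_row_labels is not None:
        row_labels = np.asarray(known_row_labels, dtype=int)
        G1 = len(np.unique(row_labels))
    else:
        emb1, _ = matrix_tsne(data, replace(config, alpha=1.0))
        pts_r = margin_points(emb1, 1.0)
        G1, g1_flag = select_marginal_G(
            pts_r, g_max=g_max, threshold=threshold, restarts=restarts, seed=seed
        )
        row_labels = kmeans_labels(pts_r, G1, restarts=restarts, seed=seed)
    if known_col_labels is not None:
        col_labels = np.asarray(known_col_labels, dtype=int)
        G0 = len(np.unique(col_labels))
    else:
        emb0, _ = matrix_tsne(data, replace(config, alpha=0.0))
        pts_c = margin_points(emb0, 0.0)
        G0, g0_flag = select_marginal_G(
            pts_c, g_max=g_max, threshold=threshold, restarts=restarts, seed=seed
        )
        col_labels = kmeans_labels(pts_c, G0, restarts=restarts, seed=seed)
    G = G0 * G1
    truth = cross_product_labels(row_labels, col_labels)

    # --- grid search --------------------------------------------------------
    scores: dict[float, float] = {}
    for a in alphas:
        emb, _ = matrix_tsne(data, replace(config, alpha=float(a)))
        scores[float(a)] = _score_embedding(
            emb.points(), truth, G, metric, seed,
            restarts=restarts, fresh_kmeans_for_ssb=fresh_kmeans_for_ssb,
        )
    best = max(scores.values())
    alpha_star = min(a for a, s in scores.items() if s >= best - 1e-12)
    return WeightSelectionReport(
        G0=G0,
        G1=G1,
        G=G,
        alphas=alphas,
        score_per_alpha=scores,
        alpha_star=alpha_star,
        metric=metric,
        row_labels=row_labels,
        col_labels=col_labels,
        seed=seed,
        g0_flagged=g0_flag,
        g1_flagged=g1_flag,
    )


def seed_perturbation_eval(
    data: MatrixFramedData,
    alpha: float,
    n_seeds: int,
    config: OptimizerConfig,
    truth: np.ndarray,
    G: int,
    metrics: Sequence[Metric] = ("ari", "nmi", "ssb_sst"),
    include_baseline: bool = False,
    baseline_perplexity: float | None = None,
    seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Stability of the embedding under random restarts.

    Runs the matrix embedding (and optionally the unstructured classical
    baseline) under ``n_seeds`` seeds, scoring each run against the supplied
    cross-product ``truth`` labels.  Returns a long-format table with one
    record per (method, seed, metric); medians/IQRs are one groupby away.
    """
    if n_seeds < 2:
        raise ValueError("need at least two seeds")
    if seeds is None:
        seeds = [config.seed + s for s in range(n_seeds)]
    truth = np.asarray(truth)
    records = []
    D_elem = None
    for s in seeds:
        cfg = replace(config, alpha=alpha, seed=int(s))
        emb, _ = matrix_tsne(data, cfg)
        for metric in metrics:
            records.append(
                {
                    "method": "matrix_tsne",
                    "seed": int(s),
                    "metric": metric,
                    "value": _score_embedding(emb.points(), truth, G, metric, int(s)),
                }
            )
        if include_baseline:
            if D_elem is None:
                D_elem = element_distance_matrix(data)
            n = D_elem.D.shape[0]
            perp = baseline_perplexity
            if perp is None:
                perp = min(30.0, n - 1)
            pts, _ = classical_tsne(D_elem, perp, cfg)
            for metric in metrics:
                records.append(
                    {
                        "method": "classical_tsne",
                        "seed": int(s),
                        "metric": metric,
                        "value": _score_embedding(pts, truth, G, metric, int(s)),
                    }
                )
    return pd.DataFrame.from_records(records)
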