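"""Planted row-group × column-group generators for all three element kinds.

Each generator plants an R×C checkerboard of group effects in an I×K grid and
returns both the dataset and the design (which carries the ground-truth
margin assignments).  Group effects are additive and orthogonal — a row
effect and a column effect, never an interaction — so each margin is
independently recoverable and the cross-product of the marginal clusters is
the element-level ground truth.

* scalar — X_ik = a_{r(i)} + b_{c(k)} + ε, ε ~ N(0, noise_sd²).  Offsets are
  spaced so the minimum pairwise *margin profile* distance equals
  ``separation`` (row offsets spaced separation/√K, column offsets
  separation/√I).  ``row_scale`` multiplies the row offsets only,
  reproducing the scale-mismatch regime in which one margin's variability
  dwarfs the other's and an unstructured element-level embedding loses the
  weaker margin.
* series — element (i,k) is a T×P sinusoid whose frequency is set by the row
  group, phase by the column group, amplitude by ``separation``, with
  additive Gaussian noise and a random per-element time shift that DTW must
  absorb.
* histogram — element (i,k) is the B-bin histogram of n_samples draws from
  N(a_{r(i)} + b_{c(k)}, sample_sd²) on one shared bin grid.

All generators are deterministic given ``design.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import HistogramElement, MatrixFramedData, SeriesElement

__all__ = ["PlantedDesign", "make_scalar_data", "make_series_data", "make_histogram_data"]


@dataclass
class PlantedDesign:
    """Planted biclustering design: sizes, assignments, effect sizes, seed."""

    I: int
    K: int
    R: int
    C: int
    row_assignment: np.ndarray
    col_assignment: np.ndarray
    separation: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0
    row_scale: float = 1.0

    def __post_init__(self) -> None:
        self.row_assignment = np.asarray(self.row_assignment, dtype=int)
        self.col_assignment = np.asarray(self.col_assignment, dtype=int)
        if self.row_assignment.shape != (self.I,) or self.col_assignment.shape != (self.K,):
            raise ValueError("assignment lengths must match I and K")
        if self.R > self.I or self.C > self.K:
            raise ValueError("cannot have more groups than rows/columns")
        if set(np.unique(self.row_assignment)) != set(range(self.R)):
            raise ValueError("row groups must be 0..R-1, every group nonempty")
        if set(np.unique(self.col_assignment)) != set(range(self.C)):
            raise ValueError("column groups must be 0..C-1, every group nonempty")
        if self.separation <= 0 or self.noise_sd < 0:
            raise ValueError("separation must be positive, noise_sd nonnegative")

    @classmethod
    def balanced(
        cls,
        I: int,
        K: int,
        R: int,
        C: int,
        separation: float = 10.0,
        noise_sd: float = 1.0,
        seed: int = 0,
        row_scale: float = 1.0,
    ) -> "PlantedDesign":
        """Contiguous, as-equal-as-possible group blocks along each margin."""
        return cls(
            I=I,
            K=K,
            R=R,
            C=C,
            row_assignment=(np.arange(I) * R) // I,
            col_assignment=(np.arange(K) * C) // K,
            separation=separation,
            noise_sd=noise_sd,
            seed=seed,
            row_scale=row_scale,
        )

    def cross_labels(self) -> np.ndarray:
        """Element-level ground truth in row-major (i, k) order."""
        return (self.row_assignment[:, None] * self.C + self.col_assignment[None, :]).ravel()


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def make_scalar_data(design: PlantedDesign) -> tuple[MatrixFramedData, PlantedDesign]:
    """Additive planted scalar data; margin profile gaps equal ``separation``."""
    rng = np.random.default_rng(design.seed)
    row_off = np.arange(design.R) * design.separation * design.row_scale / np.sqrt(design.K)
    col_off = np.arange(design.C) * design.separation / np.sqrt(design.I)
    mu = row_off[design.row_assignment][:, None] + col_off[design.col_assignment][None, :]
    X = mu + rng.normal(0.0, design.noise_sd, size=(design.I, design.K))
    data = MatrixFramedData.from_values(
        X, row_ids=_ids("r", design.I), col_ids=_ids("c", design.K)
    )
    return data, design


def make_series_data(
    design: PlantedDesign,
    T: int = 30,
    P: int = 3,
    max_shift: int | None = None,
) -> tuple[MatrixFramedData, PlantedDesign]:
    """Planted multivariate sinusoids.

    Row group r gets frequency r+1 cycles over the window; column group c gets
    phase 2πc/C (which a monotone warping cannot remove, unlike the random
    per-element time shift of up to ``max_shift`` samples, which it can).
    """
    if T < 4:
        raise ValueError("need T >= 4")
    rng = np.random.default_rng(design.seed)
    if max_shift is None:
        max_shift = max(1, T // 10)
    amp = design.separation
    t = np.arange(T)
    elems = np.empty((design.I, design.K), dtype=object)
    for i in range(design.I):
        freq = design.row_assignment[i] + 1.0
        for k in range(design.K):
            phase = 2.0 * np.pi * design.col_assignment[k] / design.C
            shift = rng.integers(0, max_shift + 1)
            vals = np.empty((T, P))
            for p in range(P):
                vals[:, p] = amp * np.sin(
                    2.0 * np.pi * freq * (t + shift) / T + phase + 2.0 * np.pi * p / P
                )
            vals += rng.normal(0.0, design.noise_sd, size=(T, P))
            elems[i, k] = SeriesElement(vals)
    data = MatrixFramedData(
        row_ids=_ids("r", design.I), col_ids=_ids("c", design.K),
        elements=elems, kind="series",
    )
    return data, design


def make_histogram_data(
    design: PlantedDesign,
    B: int = 20,
    n_samples: int = 500,
    sample_sd: float = 1.0,
) -> tuple[MatrixFramedData, PlantedDesign]:
    """Planted histogram data on one shared bin grid.

    Cell (i, k) holds the B-bin histogram of ``n_samples`` Gaussian draws
    centered at a_{r(i)} + b_{c(k)} with standard deviation ``sample_sd``;
    the two additive offsets are each spaced ``separation`` apart, so the
    population Wasserstein gap between adjacent groups is ``separation`` on
    both margins (per element, before the √K / √I margin aggregation).
    """
    if B < 2:
        raise ValueError("need B >= 2")
    rng = np.random.default_rng(design.seed)
    row_off = np.arange(design.R) * design.separation * design.row_scale
    col_off = np.arange(design.C) * design.separation
    means = (
        row_off[design.row_assignment][:, None] + col_off[design.col_assignment][None, :]
    )
    lo = means.min() - 5.0 * sample_sd
    hi = means.max() + 5.0 * sample_sd
    edges = np.linspace(lo, hi, B + 1)
    elems = np.empty((design.I, design.K), dtype=object)
    for i in range(design.I):
        for k in range(design.K):
            draws = rng.normal(means[i, k], sample_sd, size=n_samples)
            draws = np.clip(draws, lo, hi - 1e-12)
            counts, _ = np.histogram(draws, bins=edges)
            elems[i, k] = HistogramElement(edges, counts / counts.sum())
    data = MatrixFramedData(
        row_ids=_ids("r", design.I), col_ids=_ids("c", design.K),
        elements=elems, kind="histogram",
    )
    return data, design
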