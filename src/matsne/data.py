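"""Matrix-framed data: an I×K grid of typed elements with row and column labels.

A matrix-framed dataset is indexed simultaneously by a row label and a column
label, and every cell holds one element of a single kind shared by the whole
dataset: a scalar, a multivariate time series (T×P, T may vary per cell), or a
histogram (bin edges plus masses summing to one).  Rows and columns are both
first-class: the method downstream embeds every (row, column) element while
preserving group structure along each margin.

All on-disk formats are comma-delimited UTF-8 text with '.' as the decimal
mark; label order follows first appearance in the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScalarElement",
    "SeriesElement",
    "HistogramElement",
    "MatrixFramedData",
    "Embedding",
    "read_scalar_matrix",
    "write_scalar_matrix",
    "read_long_table",
    "write_long_table",
    "read_embedding",
    "write_embedding",
]

ElementKind = Literal["scalar", "series", "histogram"]

#: tolerance under which histogram masses are silently renormalized on load
_HIST_RENORM_TOL = 1e-6
#: tolerance for the stored-mass invariant
_HIST_SUM_TOL = 1e-9


class DataValidationError(ValueError):
    """Raised when a file or in-memory dataset violates the data contract."""


@dataclass(frozen=True)
class ScalarElement:
    """A single real value."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise DataValidationError(f"scalar element is not finite: {self.value!r}")


@dataclass(frozen=True)
class SeriesElement:
    """A T×P multivariate time series (T time points, P coordinates)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DataValidationError(
                f"series element must be a T×P array with T,P >= 1, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise DataValidationError("series element contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class HistogramElement:
    """A histogram: strictly increasing bin edges and masses summing to one."""

    bin_edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        if edges.ndim != 1 or masses.ndim != 1 or edges.size != masses.size + 1:
            raise DataValidationError(
                "histogram needs B+1 edges and B masses "
                f"(got {edges.size} edges, {masses.size} masses)"
            )
        if masses.size < 1:
            raise DataValidationError("histogram needs at least one bin")
        if not np.all(np.isfinite(edges)) or not np.all(np.isfinite(masses)):
            raise DataValidationError("histogram contains non-finite entries")
        if np.any(np.diff(edges) <= 0):
            raise DataValidationError("histogram bin edges must be strictly increasing")
        if np.any(masses < 0):
            raise DataValidationError("histogram masses must be nonnegative")
        total = masses.sum()
        if total <= 0:
            raise DataValidationError("histogram has zero total mass")
        if abs(total - 1.0) > _HIST_SUM_TOL:
            raise DataValidationError(
                f"histogram masses must sum to 1 (got {total!r}); "
                "renormalize before constructing the element"
            )
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "masses", masses)

    @property
    def n_bins(self) -> int:
        return self.masses.size


@dataclass
class MatrixFramedData:
    """An I×K grid of elements of one kind, with distinct row/column labels."""

    row_ids: list[str]
    col_ids: list[str]
    elements: np.ndarray  # object array of shape (I, K)
    kind: ElementKind

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(set(self.row_ids)) != len(self.row_ids):
            dup = _first_duplicate(self.row_ids)
            raise DataValidationError(f"duplicate row label {dup!r}")
        if len(set(self.col_ids)) != len(self.col_ids):
            dup = _first_duplicate(self.col_ids)
            raise DataValidationError(f"duplicate column label {dup!r}")
        if len(self.row_ids) < 2 or len(self.col_ids) < 2:
            raise DataValidationError("matrix-framed data needs I >= 2 and K >= 2")
        elems = np.empty((len(self.row_ids), len(self.col_ids)), dtype=object)
        src = np.asarray(self.elements, dtype=object)
        if src.shape != elems.shape:
            raise DataValidationError(
                f"element grid shape {src.shape} does not match labels "
                f"({len(self.row_ids)}×{len(self.col_ids)})"
            )
        expected_cls = {
            "scalar": ScalarElement,
            "series": SeriesElement,
            "histogram": HistogramElement,
        }[self.kind]
        p_dims = None
        for i in range(elems.shape[0]):
            for k in range(elems.shape[1]):
                el = src[i, k]
                if el is None:
                    raise DataValidationError(
                        f"missing element at ({self.row_ids[i]!r}, {self.col_ids[k]!r})"
                    )
                if not isinstance(el, expected_cls):
                    raise DataValidationError(
                        f"element at ({self.row_ids[i]!r}, {self.col_ids[k]!r}) is "
                        f"{type(el).__name__}, expected {expected_cls.__name__}"
                    )
                if self.kind == "series":
                    if p_dims is None:
                        p_dims = el.n_dims
                    elif el.n_dims != p_dims:
                        raise DataValidationError(
                            "inconsistent series dimensionality P: "
                            f"{el.n_dims} at ({self.row_ids[i]!r}, {self.col_ids[k]!r}) "
                            f"vs {p_dims} elsewhere"
                        )
                elems[i, k] = el
        self.elements = elems

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def values(self) -> np.ndarray:
        """Dense float matrix of the scalar values (scalar kind only)."""
        if self.kind != "scalar":
            raise DataValidationError("values() is only defined for scalar datasets")
        out = np.empty(self.shape, dtype=float)
        for i in range(self.n_rows):
            for k in range(self.n_cols):
                out[i, k] = self.elements[i, k].value
        return out

    def transpose(self) -> "MatrixFramedData":
        """Swap the roles of rows and columns."""
        return MatrixFramedData(
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            elements=self.elements.T.copy(),
            kind=self.kind,
        )

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        row_ids: Sequence[str] | None = None,
        col_ids: Sequence[str] | None = None,
    ) -> "MatrixFramedData":
        """Build a scalar-kind dataset from a dense numeric matrix."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise DataValidationError("from_values expects a 2-D array")
        n_i, n_k = values.shape
        row_ids = list(row_ids) if row_ids is not None else [f"r{i}" for i in range(n_i)]
        col_ids = list(col_ids) if col_ids is not None else [f"c{k}" for k in range(n_k)]
        elems = np.empty((n_i, n_k), dtype=object)
        for i in range(n_i):
            for k in range(n_k):
                elems[i, k] = ScalarElement(float(values[i, k]))
        return cls(row_ids=row_ids, col_ids=col_ids, elements=elems, kind="scalar")


@dataclass
class Embedding:
    """2-D coordinates for every (row, column) element: an I×K×2 array."""

    row_ids: list[str]
    col_ids: list[str]
    Y: np.ndarray  # shape (I, K, 2)

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim != 3 or Y.shape[2] != 2:
            raise DataValidationError(f"embedding must be I×K×2, got shape {Y.shape}")
        if Y.shape[0] != len(self.row_ids) or Y.shape[1] != len(self.col_ids):
            raise DataValidationError("embedding shape does not match labels")
        self.Y = Y

    @property
    def n_points(self) -> int:
        return self.Y.shape[0] * self.Y.shape[1]

    def points(self) -> np.ndarray:
        """Flattened (I·K)×2 coordinates in row-major (i, k) order."""
        return self.Y.reshape(-1, 2)


def _first_duplicate(labels: Iterable[str]) -> str:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            return lab
        seen.add(lab)
    return ""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_scalar_matrix(path: str | Path) -> MatrixFramedData:
    """Read a dense scalar matrix: header row of column labels, leading label column."""
    path = Path(path)
    rows: list[list[str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            rows.append(line.split(","))
    if len(rows) < 2:
        raise DataValidationError(f"{path}: need a header row and at least one data row")
    col_ids = [c.strip() for c in rows[0][1:]]
    width = len(col_ids)
    row_ids: list[str] = []
    body = np.empty((len(rows) - 1, width), dtype=float)
    for r, rec in enumerate(rows[1:]):
        if len(rec) - 1 != width:
            raise DataValidationError(
                f"{path}: ragged row {rec[0]!r} has {len(rec) - 1} cells, expected {width}"
            )
        row_ids.append(rec[0].strip())
        for c, cell in enumerate(rec[1:]):
            try:
                body[r, c] = float(cell)
            except ValueError as exc:
                raise DataValidationError(
                    f"{path}: non-numeric cell at row {rec[0]!r}, column {col_ids[c]!r}: "
                    f"{cell!r}"
                ) from exc
    return MatrixFramedData.from_values(body, row_ids=row_ids, col_ids=col_ids)


def write_scalar_matrix(data: MatrixFramedData, path: str | Path) -> None:
    """Write a scalar dataset as a dense labeled matrix."""
    if data.kind != "scalar":
        raise DataValidationError("write_scalar_matrix requires a scalar dataset")
    vals = data.values()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("," + ",".join(data.col_ids) + "\n")
        for i, rid in enumerate(data.row_ids):
            fh.write(rid + "," + ",".join(repr(float(v)) for v in vals[i]) + "\n")


def read_long_table(path: str | Path, kind: ElementKind) -> MatrixFramedData:
    """Read a long-format table into a dense matrix-framed dataset.

    Series tables carry (row_id, col_id, dim, time, value) with contiguous
    0-based integer times per (cell, dim); histogram tables carry
    (row_id, col_id, bin_left, bin_right, mass).  Every (row_id, col_id)
    combination must be present.  Histogram masses within 1e-6 of unit total
    are renormalized; larger deviations are an error.
    """
    path = Path(path)
    if kind == "series":
        df = pd.read_csv(
            path,
            dtype={"row_id": str, "col_id": str},
            keep_default_na=False,
        )
        required = {"row_id", "col_id", "dim", "time", "value"}
        if not required.issubset(df.columns):
            raise DataValidationError(
                f"{path}: series table needs columns {sorted(required)}"
            )
        row_ids = list(dict.fromkeys(df["row_id"]))
        col_ids = list(dict.fromkeys(df["col_id"]))
        elems = np.empty((len(row_ids), len(col_ids)), dtype=object)
        grouped = dict(tuple(df.groupby(["row_id", "col_id"], sort=False)))
        p_all = int(df["dim"].max()) + 1
        for i, rid in enumerate(row_ids):
            for k, cid in enumerate(col_ids):
                cell = grouped.get((rid, cid))
                if cell is None:
                    raise DataValidationError(f"{path}: missing cell ({rid!r}, {cid!r})")
                dims = sorted(cell["dim"].unique())
                if dims != list(range(p_all)):
                    raise DataValidationError(
                        f"{path}: cell ({rid!r}, {cid!r}) has dims {dims}, "
                        f"expected 0..{p_all - 1}"
                    )
                per_dim = []
                for p in range(p_all):
                    sub = cell[cell["dim"] == p].sort_values("time")
                    times = sub["time"].to_numpy()
                    if not np.array_equal(times, np.arange(len(times))):
                        raise DataValidationError(
                            f"{path}: cell ({rid!r}, {cid!r}) dim {p} times are not "
                            "contiguous 0-based integers"
                        )
                    per_dim.append(sub["value"].to_numpy(dtype=float))
                lengths = {len(v) for v in per_dim}
                if len(lengths) != 1:
                    raise DataValidationError(
                        f"{path}: cell ({rid!r}, {cid!r}) has unequal lengths across dims"
                    )
                elems[i, k] = SeriesElement(np.column_stack(per_dim))
        return MatrixFramedData(row_ids, col_ids, elems, "series")

    if kind == "histogram":
        df = pd.read_csv(
            path,
            dtype={"row_id": str, "col_id": str},
            keep_default_na=False,
        )
        required = {"row_id", "col_id", "bin_left", "bin_right", "mass"}
        if not required.issubset(df.columns):
            raise DataValidationError(
                f"{path}: histogram table needs columns {sorted(required)}"
            )
        row_ids = list(dict.fromkeys(df["row_id"]))
        col_ids = list(dict.fromkeys(df["col_id"]))
        elems = np.empty((len(row_ids), len(col_ids)), dtype=object)
        grouped = dict(tuple(df.groupby(["row_id", "col_id"], sort=False)))
        for i, rid in enumerate(row_ids):
            for k, cid in enumerate(col_ids):
                cell = grouped.get((rid, cid))
                if cell is None:
                    raise DataValidationError(f"{path}: missing cell ({rid!r}, {cid!r})")
                cell = cell.sort_values("bin_left")
                left = cell["bin_left"].to_numpy(dtype=float)
                right = cell["bin_right"].to_numpy(dtype=float)
                mass = cell["mass"].to_numpy(dtype=float)
                if np.any(right <= left) or np.any(left[1:] < right[:-1] - 1e-12):
                    raise DataValidationError(
                        f"{path}: cell ({rid!r}, {cid!r}) has overlapping or "
                        "unordered bins"
                    )
                if not np.allclose(left[1:], right[:-1], atol=1e-12):
                    raise DataValidationError(
                        f"{path}: cell ({rid!r}, {cid!r}) bins are not contiguous"
                    )
                total = mass.sum()
                if abs(total - 1.0) > _HIST_RENORM_TOL:
                    raise DataValidationError(
                        f"{path}: cell ({rid!r}, {cid!r}) masses sum to {total!r}, "
                        "further than 1e-6 from 1"
                    )
                edges = np.append(left, right[-1])
                elems[i, k] = HistogramElement(edges, mass / total)
        return MatrixFramedData(row_ids, col_ids, elems, "histogram")

    raise DataValidationError(f"read_long_table does not handle kind {kind!r}")


def write_long_table(data: MatrixFramedData, path: str | Path) -> None:
    """Write a series or histogram dataset in long format (inverse of read_long_table)."""
    path = Path(path)
    if data.kind == "series":
        records = []
        for i, rid in enumerate(data.row_ids):
            for k, cid in enumerate(data.col_ids):
                el = data.elements[i, k]
                for p in range(el.n_dims):
                    for t in range(el.n_times):
                        records.append((rid, cid, p, t, repr(float(el.values[t, p]))))
        with path.open("w", encoding="utf-8") as fh:
            fh.write("row_id,col_id,dim,time,value\n")
            for rec in records:
                fh.write(",".join(str(x) for x in rec) + "\n")
    elif data.kind == "histogram":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("row_id,col_id,bin_left,bin_right,mass\n")
            for i, rid in enumerate(data.row_ids):
                for k, cid in enumerate(data.col_ids):
                    el = data.elements[i, k]
                    for b in range(el.n_bins):
                        fh.write(
                            f"{rid},{cid},{float(el.bin_edges[b])!r},"
                            f"{float(el.bin_edges[b + 1])!r},{float(el.masses[b])!r}\n"
                        )
    else:
        raise DataValidationError("write_long_table handles series and histogram kinds")


def write_embedding(embedding: Embedding, path: str | Path) -> None:
    """Write an embedding as (row_id, col_id, y1, y2) records, one per element."""
    if not np.all(np.isfinite(embedding.Y)):
        raise DataValidationError("embedding contains non-finite coordinates")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("row_id,col_id,y1,y2\n")
        for i, rid in enumerate(embedding.row_ids):
            for k, cid in enumerate(embedding.col_ids):
                y1, y2 = embedding.Y[i, k]
                fh.write(f"{rid},{cid},{float(y1)!r},{float(y2)!r}\n")


def read_embedding(path: str | Path) -> Embedding:
    """Read an embedding written by :func:`write_embedding`."""
    df = pd.read_csv(path, dtype={"row_id": str, "col_id": str}, keep_default_na=False)
    row_ids = list(dict.fromkeys(df["row_id"]))
    col_ids = list(dict.fromkeys(df["col_id"]))
    Y = np.full((len(row_ids), len(col_ids), 2), np.nan)
    ridx = {r: i for i, r in enumerate(row_ids)}
    cidx = {c: k for k, c in enumerate(col_ids)}
    for rec in df.itertuples(index=False):
        Y[ridx[rec.row_id], cidx[rec.col_id]] = (float(rec.y1), float(rec.y2))
    if np.any(np.isnan(Y)):
        raise DataValidationError(f"{path}: embedding grid has missing cells")
    return Embedding(row_ids=row_ids, col_ids=col_ids, Y=Y)
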