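"""Integrated multi-block dataset model and text-format I/O.

A study is represented as one samples-by-features matrix in which
contiguous column ranges form the individual data blocks (gene
expression, microRNA expression, DNA methylation, ...).  One range may
be designated as the response block Y for the regression-flavoured
methods; the remaining ranges are the predictor blocks ``X_1..X_N``.
An optional feature-feature interaction network is stored as a
symmetric adjacency matrix whose row/column order equals the feature
order of the data matrix.

On disk a dataset is a small bundle of delimited text files tied
together by a YAML config:

* matrix file  — TSV, first row feature labels, first column sample labels;
* block table  — TSV with columns ``feature_type``, ``start``, ``end``,
  ``role`` (``x`` or ``y``); ``start``/``end`` are 1-based inclusive
  column indexes, the convention used in the file formats of the
  original MATLAB tooling;
* network file — optional undirected edge list,
  ``labelA<TAB>labelB[<TAB>weight]``.

Internally all ranges are 0-based half-open; conversion happens only at
the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "IndexRange",
    "MethodParams",
    "IntegratedDataset",
    "assemble_adjacency",
    "load_dataset",
    "write_dataset",
]


class DatasetError(ValueError):
    """Structural problem in an integrated dataset or its files."""


@dataclass(frozen=True)
class IndexRange:
    """Half-open 0-based column range ``[start, stop)``."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise DatasetError(f"invalid index range [{self.start}, {self.stop})")

    @property
    def width(self) -> int:
        return self.stop - self.start

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    @classmethod
    def from_one_based(cls, start: int, end: int) -> "IndexRange":
        """Build from a 1-based inclusive ``(start, end)`` pair."""
        if start < 1 or end < start:
            raise DatasetError(f"invalid 1-based inclusive range ({start}, {end})")
        return cls(start - 1, end)

    def to_one_based(self) -> tuple[int, int]:
        return self.start + 1, self.stop


@dataclass
class MethodParams:
    """Run configuration shared by the four factorization methods.

    ``n_modules`` is the pre-defined number of md-modules (k).  The
    multiplicative NMF solvers run ``n_restarts`` times from different
    random starts and keep the solution with the lowest objective.

    NMF-specific entries: ``thrd_module`` holds one threshold per
    member type (first entry selects samples, the following ones select
    each block's features; larger values select fewer members),
    ``lambda11/lambda12/lambda22`` weight the must-link network
    penalties, ``gamma1`` penalizes the growth of W and ``gamma2`` the
    column sparsity of the coefficient matrices.

    PLS-specific entries: candidate grids for the sparsity penalties
    (``lambda_grid`` per predictor block, ``mu_grid`` for the response)
    and the Laplacian smoothing weights (``gamma1_grid``,
    ``gamma2_grid``); the fitted penalties are chosen by k-fold
    cross-validation.  In the default ``fraction`` mode a penalty value
    c is interpreted as c times the largest gradient magnitude of the
    vector being thresholded, so the same grid is transferable across
    blocks of different scale; ``absolute`` mode applies the values
    verbatim.
    """

    n_modules: int = 5
    max_iter: int = 100
    tol: float = 1e-6
    n_restarts: int = 10
    seed: int = 0

    # NMF family
    thrd_module: Sequence[float] | None = None
    lambda11: float = 0.0
    lambda12: float = 0.0
    lambda22: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0

    # PLS family
    lambda_grid: Sequence[float] = (0.2, 0.25, 0.3)
    mu_grid: Sequence[float] = (0.1, 0.15, 0.2)
    gamma1_grid: Sequence[float] = (0.0,)
    gamma2_grid: Sequence[float] = (0.0,)
    n_folds: int = 5
    sparsity_mode: str = "fraction"
    sample_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise DatasetError("n_modules must be a positive integer")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise DatasetError("max_iter and n_restarts must be positive")
        if self.tol <= 0:
            raise DatasetError("tol must be positive")
        for name in ("lambda11", "lambda12", "lambda22", "gamma1", "gamma2"):
            if getattr(self, name) < 0:
                raise DatasetError(f"{name} must be >= 0")
        for name in ("lambda_grid", "mu_grid", "gamma1_grid", "gamma2_grid"):
            grid = tuple(float(v) for v in getattr(self, name))
            if not grid:
                raise DatasetError(f"{name} must be non-empty")
            if any(v < 0 for v in grid):
                raise DatasetError(f"{name} entries must be >= 0")
            object.__setattr__(self, name, grid)
        if self.thrd_module is not None:
            object.__setattr__(self, "thrd_module", tuple(float(v) for v in self.thrd_module))
        if self.sparsity_mode not in ("fraction", "absolute"):
            raise DatasetError("sparsity_mode must be 'fraction' or 'absolute'")

    @classmethod
    def from_dict(cls, d: dict) -> "MethodParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DatasetError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, tuple):
                out[k] = list(v)
        return out


@dataclass
class IntegratedDataset:
    """Stacked samples-by-features matrix with block structure.

    ``data`` holds all blocks side by side; ``x_blocks`` (and the
    optional ``y_block``) say which columns belong to which block.
    ``feature_types`` names each block in block order (x blocks first,
    then the y block if present).
    """

    data: np.ndarray
    x_blocks: list[IndexRange]
    y_block: IndexRange | None
    sample_labels: list[str]
    feature_labels: list[str]
    feature_types: list[str]
    net_adjacency: sp.spmatrix | None = None
    params: MethodParams | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def blocks(self) -> list[IndexRange]:
        """All block ranges in block order (x blocks, then y)."""
        out = list(self.x_blocks)
        if self.y_block is not None:
            out.append(self.y_block)
        return out

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise DatasetError("data must be a 2-d matrix")
        m, n = self.data.shape
        if not np.isfinite(self.data).all():
            raise DatasetError("data contains missing or non-finite values; "
                               "impute before building a dataset")
        if len(self.sample_labels) != m:
            raise DatasetError(f"{len(self.sample_labels)} sample labels for {m} rows")
        if len(self.feature_labels) != n:
            raise DatasetError(f"{len(self.feature_labels)} feature labels for {n} columns")
        blocks = self.blocks
        if not blocks:
            raise DatasetError("at least one block is required")
        if len(self.feature_types) != len(blocks):
            raise DatasetError("one feature_type is required per block")
        covered = np.zeros(n, dtype=bool)
        for rng in blocks:
            if rng.stop > n:
                raise DatasetError(f"block range {rng} exceeds {n} columns")
            if covered[rng.start:rng.stop].any():
                raise DatasetError("block ranges overlap")
            covered[rng.start:rng.stop] = True
        if not covered.all():
            raise DatasetError("block ranges do not cover every column")
        A = self.net_adjacency
        if A is not None:
            if A.shape != (n, n):
                raise DatasetError(f"adjacency shape {A.shape} != ({n}, {n})")
            if A.nnz:
                if A.min() < 0:
                    raise DatasetError("adjacency entries must be >= 0")
                if abs(A - A.T).max() > 1e-12:
                    raise DatasetError("adjacency must be symmetric")

    # -- views -------------------------------------------------------------

    def split_blocks(self) -> tuple[list[np.ndarray], np.ndarray | None]:
        """Partition ``data`` into the X block matrices and optional Y."""
        xs = [self.data[:, r.start:r.stop] for r in self.x_blocks]
        y = None if self.y_block is None else self.data[:, self.y_block.start:self.y_block.stop]
        return xs, y

    def block_feature_labels(self, rng: IndexRange) -> list[str]:
        return self.feature_labels[rng.start:rng.stop]

    def adjacency_block(self, rows: IndexRange, cols: IndexRange) -> np.ndarray:
        """Dense sub-block of the network adjacency for two column ranges."""
        if self.net_adjacency is None:
            return np.zeros((rows.width, cols.width))
        return np.asarray(
            self.net_adjacency[rows.start:rows.stop, cols.start:cols.stop].todense()
        )


def assemble_adjacency(A11: np.ndarray, A12: np.ndarray, A22: np.ndarray) -> sp.csr_matrix:
    """Assemble the two-block network adjacency ``[[A11, A12], [A12.T, A22]]``.

    ``A11`` and ``A22`` are the within-block interaction networks of
    blocks 1 and 2 (either may be all zeros when no such network
    exists) and ``A12`` the between-block network.  The result is
    symmetric with a zero diagonal; self-links carry no information for
    must-link penalties and are dropped.
    """
    A11 = np.asarray(A11, dtype=float)
    A12 = np.asarray(A12, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    n1, n2 = A12.shape
    if A11.shape != (n1, n1) or A22.shape != (n2, n2):
        raise DatasetError(
            f"non-conforming adjacency shapes: A11 {A11.shape}, A12 {A12.shape}, A22 {A22.shape}"
        )
    for name, block in (("A11", A11), ("A12", A12), ("A22", A22)):
        if (block < 0).any():
            raise DatasetError(f"{name} has negative entries")
    A11 = (A11 + A11.T) / 2.0
    A22 = (A22 + A22.T) / 2.0
    full = np.block([[A11, A12], [A12.T, A22]])
    np.fill_diagonal(full, 0.0)
    return sp.csr_matrix(full)


# ---------------------------------------------------------------------------
# I/O


def _read_block_table(path: str, n_total: int) -> tuple[list[IndexRange], IndexRange | None, list[str]]:
    table = pd.read_csv(path, sep="\t")
    required = {"feature_type", "start", "end", "role"}
    if not required.issubset(table.columns):
        raise DatasetError(f"block table {path} must have columns {sorted(required)}")
    x_blocks: list[IndexRange] = []
    y_block: IndexRange | None = None
    types: list[str] = []
    y_type: str | None = None
    for _, row in table.iterrows():
        rng = IndexRange.from_one_based(int(row["start"]), int(row["end"]))
        if rng.stop > n_total:
            raise DatasetError(
                f"block range ({row['start']}, {row['end']}) outside matrix with {n_total} columns"
            )
        role = str(row["role"]).lower()
        if role == "x":
            x_blocks.append(rng)
            types.append(str(row["feature_type"]))
        elif role == "y":
            if y_block is not None:
                raise DatasetError("more than one response (y) block")
            y_block = rng
            y_type = str(row["feature_type"])
        else:
            raise DatasetError(f"unknown block role {row['role']!r}")
    if y_type is not None:
        types.append(y_type)
    return x_blocks, y_block, types


def _read_edge_list(path: str, feature_labels: list[str]) -> sp.csr_matrix:
    edges = pd.read_csv(path, sep="\t", header=None, comment="#")
    if edges.shape[1] not in (2, 3):
        raise DatasetError(f"network file {path} must have 2 or 3 columns")
    index: dict[str, int] = {}
    for i, label in enumerate(feature_labels):
        if label in index:
            raise DatasetError(
                f"duplicate feature label {label!r}: labels must be unique to resolve network edges"
            )
        index[label] = i
    n = len(feature_labels)
    weights: dict[tuple[int, int], float] = {}
    for tup in edges.itertuples(index=False):
        a, b = str(tup[0]), str(tup[1])
        w = float(tup[2]) if len(tup) == 3 else 1.0
        if w < 0:
            raise DatasetError(f"negative edge weight for ({a}, {b})")
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise DatasetError(f"network node {missing!r} is not a feature label")
        ia, ib = index[a], index[b]
        if ia == ib:
            continue  # self-links are meaningless for must-link penalties
        key = (min(ia, ib), max(ia, ib))
        weights[key] = max(weights.get(key, 0.0), w)  # repeated lines do not stack
    rows, cols, vals = [], [], []
    for (ia, ib), w in weights.items():
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def load_dataset(config_path: str | os.PathLike) -> IntegratedDataset:
    """Load a dataset bundle from its YAML config.

    The config names the matrix file, the block table and optionally a
    network edge list and a ``params`` mapping; relative paths are
    resolved against the config's directory.
    """
    config_path = os.fspath(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "matrix" not in cfg or "blocks" not in cfg:
        raise DatasetError(f"config {config_path} must define 'matrix' and 'blocks'")
    base = os.path.dirname(os.path.abspath(config_path))

    def _resolve(p: str) -> str:
        p = os.path.join(base, p) if not os.path.isabs(p) else p
        if not os.path.exists(p):
            raise DatasetError(f"file not found: {p}")
        return p

    matrix_path = _resolve(cfg["matrix"])
    with open(matrix_path) as fh:
        # read the header ourselves: pandas mangles duplicate labels
        feature_labels = fh.readline().rstrip("\n").split("\t")[1:]
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0, skiprows=1, header=None)
    try:
        data = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise DatasetError(f"non-numeric cell in matrix file: {exc}") from exc
    if frame.isna().to_numpy().any():
        raise DatasetError("matrix file contains missing values; impute beforehand")
    sample_labels = [str(s) for s in frame.index]
    x_blocks, y_block, feature_types = _read_block_table(_resolve(cfg["blocks"]), data.shape[1])

    adjacency = None
    if cfg.get("network"):
        adjacency = _read_edge_list(_resolve(cfg["network"]), feature_labels)

    params = MethodParams.from_dict(cfg["params"]) if cfg.get("params") else None
    return IntegratedDataset(
        data=data,
        x_blocks=x_blocks,
        y_block=y_block,
        sample_labels=sample_labels,
        feature_labels=feature_labels,
        feature_types=feature_types,
        net_adjacency=adjacency,
        params=params,
    )


def write_dataset(ds: IntegratedDataset, directory: str | os.PathLike, name: str = "dataset") -> str:
    """Write a dataset bundle; returns the path of the YAML config."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)

    matrix_file = f"{name}.matrix.tsv"
    frame = pd.DataFrame(ds.data, index=ds.sample_labels, columns=ds.feature_labels)
    frame.to_csv(os.path.join(directory, matrix_file), sep="\t", float_format="%.10g")

    blocks_file = f"{name}.blocks.tsv"
    rows = []
    for ftype, rng in zip(ds.feature_types, ds.blocks):
        role = "y" if (ds.y_block is not None and rng == ds.y_block) else "x"
        start, end = rng.to_one_based()
        rows.append({"feature_type": ftype, "start": start, "end": end, "role": role})
    pd.DataFrame(rows).to_csv(os.path.join(directory, blocks_file), sep="\t", index=False)

    cfg: dict = {"matrix": matrix_file, "blocks": blocks_file}
    if ds.net_adjacency is not None and ds.net_adjacency.nnz:
        network_file = f"{name}.network.tsv"
        coo = sp.triu(ds.net_adjacency, k=1).tocoo()
        with open(os.path.join(directory, network_file), "w") as fh:
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{ds.feature_labels[i]}\t{ds.feature_labels[j]}\t{w:.10g}\n")
        cfg["network"] = network_file
    if ds.params is not None:
        cfg["params"] = ds.params.to_dict()

    config_path = os.path.join(directory, f"{name}.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return config_path
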