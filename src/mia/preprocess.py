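"""Transformations applied before fitting.

The NMF-family solvers require non-negative input; real-valued blocks
are expanded column-wise into positive and negative parts.  The
PLS-family solvers require column-centered input.  Network penalties
use the symmetric normalized graph Laplacian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["NonnegSplit", "nonneg_split", "center_columns", "normalized_laplacian"]

logger = logging.getLogger(__name__)


@dataclass
class NonnegSplit:
    """Non-negative expansion of a real matrix.

    ``data`` is ``[max(X, 0) | max(-X, 0)]`` (width ``2 n``).  Column
    ``j`` and column ``j + n`` are the positive and negative copies of
    original column ``j``; ``origin[c]`` maps an expanded column back
    to its original index and ``sign[c]`` is +1 for positive copies,
    -1 for negative ones.  ``X == data[:, :n] - data[:, n:]`` exactly.
    """

    data: np.ndarray
    origin: np.ndarray
    sign: np.ndarray

    @property
    def n_original(self) -> int:
        return self.data.shape[1] // 2

    def reconstruct(self) -> np.ndarray:
        n = self.n_original
        return self.data[:, :n] - self.data[:, n:]


def nonneg_split(X: np.ndarray) -> NonnegSplit:
    """Expand a real matrix into its non-negative parts.

    Used so that data with negative entries (z-scores, log ratios,
    copy-number segments) can enter a non-negative factorization; the
    expansion doubles the feature count and thereby changes the data
    geometry somewhat, which is inherent to the transform.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    out = NonnegSplit(
        data=np.hstack([np.maximum(X, 0.0), np.maximum(-X, 0.0)]),
        origin=np.concatenate([np.arange(n), np.arange(n)]),
        sign=np.concatenate([np.ones(n), -np.ones(n)]),
    )
    if (X < 0).any():
        logger.warning(
            "input block contains negative entries; applying the "
            "positive/negative split (doubles the feature count)"
        )
    return out


def center_columns(X: np.ndarray, scale: bool = False) -> np.ndarray:
    """Column-center a matrix; optionally scale columns to unit variance.

    Constant columns cannot be scaled; they are left at zero and
    reported through the module logger.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to center")
    out = X - X.mean(axis=0, keepdims=True)
    # columns constant up to floating-point rounding stay at zero
    constant = np.ptp(X, axis=0) <= 1e-12 * (1.0 + np.abs(X).max(axis=0))
    out[:, constant] = 0.0
    if scale:
        sd = out.std(axis=0, ddof=1, keepdims=True)
        constant = constant | (sd[0] == 0)
        if constant.any():
            logger.info("%d constant column(s) left at zero during scaling", int(constant.sum()))
        sd[:, constant] = 1.0
        out = out / sd
        out[:, constant] = 0.0
    return out


def normalized_laplacian(A: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Symmetric normalized Laplacian ``L = D^{-1/2} (D - A) D^{-1/2}``.

    ``A`` is a symmetric non-negative adjacency matrix; ``d_kk`` is the
    sum of the k-th column.  Rows/columns of isolated nodes are zero
    (their ``D^{-1/2}`` entry is taken as 0), which keeps L finite and
    positive semidefinite.
    """
    if sp.issparse(A):
        A = np.asarray(A.todense())
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if (A < 0).any():
        raise ValueError("adjacency entries must be >= 0")
    deg = A.sum(axis=0)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = -A * np.outer(inv_sqrt, inv_sqrt)
    L[np.diag_indices_from(L)] += np.where(deg > 0, 1.0, 0.0)
    # exact symmetry despite floating-point rounding
    return (L + L.T) / 2.0
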