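"""Joint and network-regularized non-negative matrix factorization.

Both solvers share one basis matrix W (samples x k) across all data
blocks and one coefficient matrix H_i (k x n_i) per block, so that
``X_i ~ W H_i`` for every block simultaneously.  A column of W together
with the matching rows of the H_i defines one candidate md-module: the
samples loading highly on the column and the features loading highly on
the row share a coherent high-signal pattern across blocks.

``fit_jnmf`` minimizes ``sum_i ||X_i - W H_i||_F^2`` for any number of
blocks.  ``fit_snmnmf`` handles the two-block case and augments the
objective with must-link network rewards ``lambda_ij Tr(H_i A_ij
H_j^T)`` (within-block networks A11/A22 and the between-block network
A12), a growth penalty ``gamma1 ||W||_F^2`` and a column-sparsity
penalty ``gamma2 sum_cols ||h||_1^2``.

The solvers use multiplicative updates (the standard construction that
splits the objective gradient into its non-negative parts, placing the
negative part in the numerator and the positive part in the
denominator) and keep the best of ``n_restarts`` random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import MethodParams

__all__ = ["FactorizationResult", "fit_jnmf", "fit_snmnmf"]

_EPS = 1e-12


@dataclass
class FactorizationResult:
    """Best-of-restarts solution of a joint factorization."""

    W: np.ndarray
    H_list: list[np.ndarray]
    objective_trace: list[float]
    restart_objectives: list[float]
    params_used: MethodParams
    seed: int
    method: str = "jnmf"

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def reconstruct(self, i: int) -> np.ndarray:
        return self.W @ self.H_list[i]


def _check_blocks(blocks: list[np.ndarray], k: int) -> tuple[int, list[int]]:
    if not blocks:
        raise ValueError("need at least one block")
    m = blocks[0].shape[0]
    widths = []
    for i, X in enumerate(blocks):
        if X.ndim != 2 or X.shape[0] != m:
            raise ValueError(f"block {i + 1} does not share the sample dimension")
        if (X < 0).any():
            raise ValueError(
                f"block {i + 1} has negative entries; apply nonneg_split before an NMF fit"
            )
        widths.append(X.shape[1])
    if not (1 <= k < min(m, min(widths))):
        raise ValueError(f"k={k} out of range for shapes {[(m, n) for n in widths]}")
    return m, widths


def _objective(
    blocks: list[np.ndarray],
    W: np.ndarray,
    H: list[np.ndarray],
    nets: list[tuple[int, int, float, np.ndarray]],
    gamma1: float,
    gamma2: float,
) -> float:
    obj = sum(float(np.linalg.norm(X - W @ Hi, "fro") ** 2) for X, Hi in zip(blocks, H))
    for i, j, lam, A in nets:
        obj -= lam * float(np.trace(H[i] @ A @ H[j].T))
    if gamma1 > 0:
        obj += gamma1 * float(np.linalg.norm(W, "fro") ** 2)
    if gamma2 > 0:
        obj += gamma2 * float(sum((Hi.sum(axis=0) ** 2).sum() for Hi in H))
    return obj


def _fit_once(
    blocks: list[np.ndarray],
    k: int,
    nets: list[tuple[int, int, float, np.ndarray]],
    gamma1: float,
    gamma2: float,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    m = blocks[0].shape[0]
    widths = [X.shape[1] for X in blocks]
    total_sq = sum(float(np.linalg.norm(X, "fro") ** 2) for X in blocks)
    scale = np.sqrt(total_sq / (k * m * sum(widths))) if total_sq > 0 else 1.0
    W = rng.uniform(size=(m, k)) * scale
    H = [rng.uniform(size=(k, n)) * scale for n in widths]

    trace: list[float] = []
    prev = None
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_iter):
            # W update: numerator sum_i X_i H_i^T, denominator W sum_i H_i H_i^T
            # (+ gamma1 W)
            num = sum(X @ Hi.T for X, Hi in zip(blocks, H))
            gram = sum(Hi @ Hi.T for Hi in H)
            den = W @ gram + gamma1 * W + _EPS
            W = W * (num / den)

            WtW = W.T @ W
            for i, X in enumerate(blocks):
                num_h = W.T @ X
                for a, b, lam, A in nets:
                    # reward terms from Tr(H_a A H_b^T) enter the numerator
                    if a == i and b == i:
                        num_h = num_h + lam * (H[i] @ A)
                    elif a == i:
                        num_h = num_h + 0.5 * lam * (H[b] @ A.T)
                    elif b == i:
                        num_h = num_h + 0.5 * lam * (H[a] @ A)
                den_h = WtW @ H[i] + _EPS
                if gamma2 > 0:
                    den_h = den_h + gamma2 * np.broadcast_to(H[i].sum(axis=0), H[i].shape)
                H[i] = H[i] * (num_h / den_h)

            obj = _objective(blocks, W, H, nets, gamma1, gamma2)
            if not np.isfinite(obj):
                # a reward weight too large for its gamma2 counterweight can
                # make the iteration diverge; discard this restart
                trace.append(np.inf)
                break
            trace.append(obj)
            if prev is not None and abs(obj - prev) / max(abs(trace[0]), _EPS) < tol:
                break
            prev = obj
    return W, H, trace


def _fit_multi_restart(
    blocks: list[np.ndarray],
    params: MethodParams,
    nets: list[tuple[int, int, float, np.ndarray]],
    gamma1: float,
    gamma2: float,
    method: str,
) -> FactorizationResult:
    blocks = [np.asarray(X, dtype=float) for X in blocks]
    _check_blocks(blocks, params.n_modules)
    best: tuple[np.ndarray, list[np.ndarray], list[float]] | None = None
    restart_objectives: list[float] = []
    for r in range(params.n_restarts):
        rng = np.random.default_rng(params.seed + r)
        W, H, trace = _fit_once(
            blocks, params.n_modules, nets, gamma1, gamma2, params.max_iter, params.tol, rng
        )
        restart_objectives.append(trace[-1])
        if best is None or trace[-1] < best[2][-1]:  # ties keep the earlier restart
            best = (W, H, trace)
    assert best is not None
    if not np.isfinite(best[2][-1]):
        raise ValueError(
            "every restart diverged; reduce the network reward weights or "
            "increase gamma2"
        )
    return FactorizationResult(
        W=best[0],
        H_list=best[1],
        objective_trace=best[2],
        restart_objectives=restart_objectives,
        params_used=params,
        seed=params.seed,
        method=method,
    )


def fit_jnmf(blocks: list[np.ndarray], params: MethodParams) -> FactorizationResult:
    """Jointly factorize any number of non-negative blocks.

    Minimizes ``sum_i ||X_i - W H_i||_F^2`` subject to ``W, H_i >= 0``
    by multiplicative updates, restarting ``params.n_restarts`` times
    and returning the solution with the lowest objective.
    """
    return _fit_multi_restart(blocks, params, nets=[], gamma1=0.0, gamma2=0.0, method="jnmf")


def fit_snmnmf(
    X1: np.ndarray,
    X2: np.ndarray,
    A11: np.ndarray | None,
    A12: np.ndarray | None,
    A22: np.ndarray | None,
    params: MethodParams,
) -> FactorizationResult:
    """Two-block joint NMF with must-link network regularization.

    Minimizes::

        sum_i ||X_i - W H_i||_F^2
          - lambda11 Tr(H1 A11 H1^T) - lambda12 Tr(H1 A12 H2^T)
          - lambda22 Tr(H2 A22 H2^T)
          + gamma1 ||W||_F^2 + gamma2 sum_cols ||h||_1^2

    A network whose weight is zero (or whose adjacency is absent or all
    zeros) contributes nothing; with all penalties zero the iterate
    sequence coincides with ``fit_jnmf`` on ``(X1, X2)`` for the same
    seed.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    n1, n2 = X1.shape[1], X2.shape[1]
    nets: list[tuple[int, int, float, np.ndarray]] = []
    for (i, j, lam, A, shape) in (
        (0, 0, params.lambda11, A11, (n1, n1)),
        (0, 1, params.lambda12, A12, (n1, n2)),
        (1, 1, params.lambda22, A22, (n2, n2)),
    ):
        if lam > 0 and A is not None:
            A = np.asarray(A, dtype=float)
            if A.shape != shape:
                raise ValueError(f"adjacency A{i + 1}{j + 1} has shape {A.shape}, expected {shape}")
            if A.any():
                nets.append((i, j, lam, A))
    return _fit_multi_restart(
        [X1, X2], params, nets=nets, gamma1=params.gamma1, gamma2=params.gamma2, method="snmnmf"
    )
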