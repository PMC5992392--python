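"""Partial least squares: plain NIPALS, sparse multi-block, and
network-regularized variants, with deflation and cross-validated
penalty selection.

All solvers extract one latent component at a time.  A component
consists of unit-norm weight vectors ``w_i`` (one per predictor block)
and ``q`` (response block), block scores ``t_i = X_i w_i``, a response
score ``u = Y q`` and, for the multi-block model, unit-norm block
combination weights ``b`` with super score ``t = sum_i b_i t_i``.

* ``fit_pls_component`` maximizes ``[cov(Xw, Yq)]^2`` under unit norms
  (classical NIPALS; the solution is the leading singular pair of
  ``X^T Y``).
* ``fit_smbpls_component`` maximizes ``cov(t, u) - sum_i lambda_i
  ||w_i||_1 - mu ||q||_1`` via alternating soft-thresholded updates.
* ``fit_snpls_component`` additionally smooths ``w`` and ``q`` over
  prior feature networks through normalized-Laplacian quadratic
  penalties ``gamma1 w^T L1 w`` and ``gamma2 q^T L2 q``.

Successive components are obtained by regression-mode deflation:
each predictor block is deflated by its own score and the response by
the super score, so the extracted structure is removed before the next
component is sought.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import cg as _conjugate_gradient

from .datasets import MethodParams
from .preprocess import center_columns

__all__ = [
    "PLSComponent",
    "LatentComponentSet",
    "fit_pls_component",
    "deflate",
    "fit_smbpls_component",
    "fit_snpls_component",
    "cross_validate_params",
    "fit_multiblock",
]

_EPS = 1e-12


class SparsityError(ValueError):
    """A sparsity penalty removed every coefficient of a weight vector."""


@dataclass
class PLSComponent:
    """One latent component of a (multi-block) PLS model."""

    w_list: list[np.ndarray]
    q: np.ndarray
    t_list: list[np.ndarray]
    t: np.ndarray
    u: np.ndarray
    b: np.ndarray | None = None
    p_list: list[np.ndarray] = field(default_factory=list)
    q_loading: np.ndarray | None = None
    n_inner_iterations: int = 0
    lambdas: list[float] = field(default_factory=list)
    mu: float = 0.0
    gammas: tuple[float, float] = (0.0, 0.0)

    @property
    def w(self) -> np.ndarray:
        if len(self.w_list) != 1:
            raise ValueError("component has more than one predictor block")
        return self.w_list[0]


@dataclass
class LatentComponentSet:
    """Sequentially extracted components plus the selection metadata."""

    components: list[PLSComponent]
    method: str
    params_used: MethodParams
    selected_lambda: float
    selected_mu: float
    selected_gammas: tuple[float, float]
    cv_table: list[dict] = field(default_factory=list)
    folds: list[np.ndarray] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    nrm = float(np.linalg.norm(v))
    if nrm <= _EPS:
        raise ValueError(f"cannot normalize all-zero {what}")
    return v / nrm


def _soft_threshold(v: np.ndarray, penalty: float, mode: str) -> np.ndarray:
    if penalty <= 0:
        return v.copy()
    thr = penalty * np.abs(v).max() if mode == "fraction" else penalty
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    """Covariance of two zero-mean score vectors."""
    return float(a @ b) / (len(a) - 1)


def _fix_signs(comp: PLSComponent) -> PLSComponent:
    """Resolve the joint sign ambiguity: largest-|entry| of q positive."""
    s = np.sign(comp.q[int(np.argmax(np.abs(comp.q)))])
    if s < 0:
        comp.q = -comp.q
        comp.u = -comp.u
        comp.w_list = [-w for w in comp.w_list]
        comp.t_list = [-t for t in comp.t_list]
        comp.t = -comp.t
        comp.p_list = [-p for p in comp.p_list]
        if comp.q_loading is not None:
            comp.q_loading = -comp.q_loading
    return comp


# ---------------------------------------------------------------------------
# plain PLS


def fit_pls_component(
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSComponent:
    """Extract one classical PLS component by NIPALS.

    ``X`` and ``Y`` must be column-centered.  Maximizes
    ``[cov(Xw, Yq)]^2`` under ``||w||_2 = ||q||_2 = 1``; the fixed
    point is the leading singular pair of ``X^T Y``.  Loadings are the
    regression coefficients of the data on the scores,
    ``p = X^T t / (t^T t)`` and ``q_loading = Y^T u / (u^T u)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not X.any() or not Y.any():
        raise ValueError("X and Y must be nonzero to extract a PLS component")
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not u.any():
        u = Y.sum(axis=1)
    w = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w_new = _unit(X.T @ u, "weight vector w")
        t = X @ w_new
        q = _unit(Y.T @ t, "weight vector q")
        u = Y @ q
        if w is not None and np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    t = X @ w
    comp = PLSComponent(
        w_list=[w],
        q=q,
        t_list=[t],
        t=t,
        u=u,
        b=None,
        p_list=[X.T @ t / max(float(t @ t), _EPS)],
        q_loading=Y.T @ u / max(float(u @ u), _EPS),
        n_inner_iterations=n_iter,
    )
    return _fix_signs(comp)


def deflate(
    X: np.ndarray,
    Y: np.ndarray,
    t: np.ndarray,
    mode: str = "regression",
    p: np.ndarray | None = None,
    q: np.ndarray | None = None,
    u: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove a rank-one explained part from X and Y.

    ``regression`` mode treats t as a predictor of Y:
    ``X' = X - t p^T`` and ``Y' = Y - t t^T Y / (t^T t)`` (so that
    ``Y'^T t = 0``).  ``symmetric`` mode deflates each matrix by its
    own score: ``X' = X - t p^T``, ``Y' = Y - u q^T``.
    """
    tt = float(t @ t)
    if tt <= _EPS:
        raise ValueError("zero score vector; cannot deflate")
    if p is None:
        p = X.T @ t / tt
    Xd = X - np.outer(t, p)
    if mode == "regression":
        Yd = Y - np.outer(t, t @ Y) / tt
    elif mode == "symmetric":
        if u is None:
            raise ValueError("symmetric deflation requires u")
        uu = float(u @ u)
        if uu <= _EPS:
            raise ValueError("zero response score; cannot deflate")
        if q is None:
            q = Y.T @ u / uu
        Yd = Y - np.outer(u, q)
    else:
        raise ValueError(f"unknown deflation mode {mode!r}")
    return Xd, Yd


# ---------------------------------------------------------------------------
# sparse multi-block PLS


def _warm_start_u(blocks: list[np.ndarray], Y: np.ndarray) -> np.ndarray:
    """Initial response score: solution of the unconstrained PLS problem.

    The first component of plain PLS on the concatenated predictor
    matrix is used as starting point, which speeds up and stabilizes
    the constrained alternations compared to a random start.
    """
    concat = blocks[0] if len(blocks) == 1 else np.hstack(blocks)
    comp = fit_pls_component(concat, Y)
    return comp.u.copy()


def fit_smbpls_component(
    blocks: list[np.ndarray],
    Y: np.ndarray,
    lambdas: list[float] | float,
    mu: float,
    sparsity_mode: str = "fraction",
    max_iter: int = 200,
    tol: float = 1e-6,
    u0: np.ndarray | None = None,
) -> PLSComponent:
    """Extract one sparse multi-block PLS component.

    Alternates, starting from the unconstrained PLS solution::

        w_i = normalize(soft_threshold(X_i^T u, lambda_i));  t_i = X_i w_i
        b_i ~ cov(t_i, u), normalized to ||b||_2 = 1;        t = sum b_i t_i
        q   = normalize(soft_threshold(Y^T t, mu));          u = Y q

    until the weight vectors stabilize.  In ``fraction`` mode each
    penalty is the given fraction of the largest gradient magnitude of
    the vector being thresholded.  A penalty that zeroes out an entire
    weight vector raises :class:`SparsityError` naming the block.
    """
    blocks = [np.asarray(X, dtype=float) for X in blocks]
    Y = np.asarray(Y, dtype=float)
    n_blocks = len(blocks)
    lams = [float(lambdas)] * n_blocks if np.isscalar(lambdas) else [float(l) for l in lambdas]
    if len(lams) != n_blocks:
        raise ValueError(f"{len(lams)} lambdas for {n_blocks} blocks")
    u = _warm_start_u(blocks, Y) if u0 is None else np.asarray(u0, dtype=float).copy()

    w_list = [np.zeros(X.shape[1]) for X in blocks]
    q = np.zeros(Y.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_w = []
        t_list = []
        for i, X in enumerate(blocks):
            g = _soft_threshold(X.T @ u, lams[i], sparsity_mode)
            if not g.any():
                raise SparsityError(
                    f"sparsity too aggressive: lambda={lams[i]} zeroes block {i + 1}"
                )
            wi = _unit(g, f"w of block {i + 1}")
            new_w.append(wi)
            t_list.append(X @ wi)
        b = np.array([_cov(ti, u) for ti in t_list])
        b = _unit(b, "block combination weights b")
        t = sum(bi * ti for bi, ti in zip(b, t_list))
        g = _soft_threshold(Y.T @ t, mu, sparsity_mode)
        if not g.any():
            raise SparsityError(f"sparsity too aggressive: mu={mu} zeroes the response weights")
        q_new = _unit(g, "q")
        u = Y @ q_new
        delta = max(
            max(np.abs(wn - wo).max() for wn, wo in zip(new_w, w_list)),
            np.abs(q_new - q).max(),
        )
        w_list, q = new_w, q_new
        if delta < tol:
            break

    comp = PLSComponent(
        w_list=w_list,
        q=q,
        t_list=t_list,
        t=t,
        u=u,
        b=b,
        p_list=[X.T @ ti / max(float(ti @ ti), _EPS) for X, ti in zip(blocks, t_list)],
        q_loading=Y.T @ u / max(float(u @ u), _EPS),
        n_inner_iterations=n_iter,
        lambdas=lams,
        mu=float(mu),
    )
    return _fix_signs(comp)


# ---------------------------------------------------------------------------
# sparse network-regularized PLS


def _smooth(gradient: np.ndarray, L: np.ndarray | None, gamma: float) -> np.ndarray:
    """Solve ``(I + gamma L) z = gradient`` (conjugate gradient)."""
    if L is None or gamma <= 0:
        return gradient
    n = len(gradient)
    A = np.eye(n) + gamma * L
    z, info = _conjugate_gradient(A, gradient, rtol=1e-10, maxiter=10 * n)
    if info != 0:  # fall back to a direct solve on hard instances
        z = np.linalg.solve(A, gradient)
    return z


def fit_snpls_component(
    X: np.ndarray,
    Y: np.ndarray,
    L1: np.ndarray | None,
    L2: np.ndarray | None,
    gamma1: float,
    gamma2: float,
    lam: float,
    mu: float,
    sparsity_mode: str = "fraction",
    max_iter: int = 200,
    tol: float = 1e-6,
    u0: np.ndarray | None = None,
) -> PLSComponent:
    """Extract one sparse network-regularized PLS component.

    Targets ``cov(t, u) - gamma1 w^T L1 w - gamma2 q^T L2 q
    - lam ||w||_1 - mu ||q||_1`` with unit-norm w and q, where L1/L2
    are normalized Laplacians of prior networks over the X and Y
    features (either may be absent).  Each inner update first smooths
    the gradient over the network, ``z = (I + gamma L)^{-1} X^T u``,
    then soft-thresholds and normalizes.  With all penalties zero this
    reduces exactly to plain NIPALS.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    u = _warm_start_u([X], Y) if u0 is None else np.asarray(u0, dtype=float).copy()
    w = np.zeros(X.shape[1])
    q = np.zeros(Y.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = _smooth(X.T @ u, L1, gamma1)
        g = _soft_threshold(z, lam, sparsity_mode)
        if not g.any():
            raise SparsityError(f"sparsity too aggressive: lambda={lam} zeroes w")
        w_new = _unit(g, "w")
        t = X @ w_new
        z = _smooth(Y.T @ t, L2, gamma2)
        g = _soft_threshold(z, mu, sparsity_mode)
        if not g.any():
            raise SparsityError(f"sparsity too aggressive: mu={mu} zeroes q")
        q_new = _unit(g, "q")
        u = Y @ q_new
        delta = max(np.abs(w_new - w).max(), np.abs(q_new - q).max())
        w, q = w_new, q_new
        if delta < tol:
            break

    comp = PLSComponent(
        w_list=[w],
        q=q,
        t_list=[t],
        t=t,
        u=u,
        b=None,
        p_list=[X.T @ t / max(float(t @ t), _EPS)],
        q_loading=Y.T @ u / max(float(u @ u), _EPS),
        n_inner_iterations=n_iter,
        lambdas=[float(lam)],
        mu=float(mu),
        gammas=(float(gamma1), float(gamma2)),
    )
    return _fix_signs(comp)


# ---------------------------------------------------------------------------
# cross-validated penalty selection


def make_folds(m: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic partition of ``range(m)`` into ``n_folds`` folds."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    perm = np.random.default_rng(seed).permutation(m)
    folds = [np.sort(perm[i::n_folds]) for i in range(n_folds)]
    if min(len(f) for f in folds) < 2:
        raise ValueError(f"{n_folds} folds over {m} samples leaves a fold with < 2 samples")
    return folds


def _fit_component(
    method: str,
    blocks: list[np.ndarray],
    Y: np.ndarray,
    lam: float,
    mu: float,
    gammas: tuple[float, float],
    L1: np.ndarray | None,
    L2: np.ndarray | None,
    sparsity_mode: str,
    u0: np.ndarray | None = None,
) -> PLSComponent:
    if method == "smbpls":
        return fit_smbpls_component(blocks, Y, lam, mu, sparsity_mode, u0=u0)
    if method == "snpls":
        if len(blocks) != 1:
            raise ValueError("snpls takes exactly one predictor block")
        return fit_snpls_component(
            blocks[0], Y, L1, L2, gammas[0], gammas[1], lam, mu, sparsity_mode, u0=u0
        )
    raise ValueError(f"unknown PLS method {method!r}")


def cross_validate_params(
    method: str,
    blocks: list[np.ndarray],
    Y: np.ndarray,
    params: MethodParams,
    L1: np.ndarray | None = None,
    L2: np.ndarray | None = None,
) -> tuple[dict, list[dict], list[np.ndarray]]:
    """Select sparsity (and smoothing) penalties by k-fold CV.

    For every candidate combination the first component is fitted on
    each training fold and scored by the absolute covariance between
    the held-out super score and response score; the combination with
    the highest mean held-out score wins, with ties resolved toward
    larger penalties (the sparser, smoother model).  Returns the
    selected combination, the full CV table and the fold index sets.
    """
    folds = make_folds(Y.shape[0], params.n_folds, params.seed)
    all_idx = np.arange(Y.shape[0])
    combos = list(
        itertools.product(params.lambda_grid, params.mu_grid,
                          params.gamma1_grid, params.gamma2_grid)
    )
    # ascending total penalty so that later ties prefer sparser models
    combos.sort(key=lambda c: (sum(c), c))
    best: dict | None = None
    table: list[dict] = []
    for lam, mu, g1, g2 in combos:
        scores = []
        for held in folds:
            train = np.setdiff1d(all_idx, held)
            blocks_tr = [center_columns(X[train]) for X in blocks]
            Y_tr = center_columns(Y[train])
            try:
                comp = _fit_component(
                    method, blocks_tr, Y_tr, lam, mu, (g1, g2), L1, L2, params.sparsity_mode
                )
            except SparsityError:
                scores.append(-np.inf)
                continue
            # apply training weights to held-out rows (training-mean centered)
            t_held = np.zeros(len(held))
            for i, X in enumerate(blocks):
                Xh = X[held] - X[train].mean(axis=0)
                ti = Xh @ comp.w_list[i]
                bi = comp.b[i] if comp.b is not None else 1.0
                t_held = t_held + bi * ti
            u_held = (Y[held] - Y[train].mean(axis=0)) @ comp.q
            scores.append(abs(_cov(t_held, u_held)))
        mean_score = float(np.mean(scores))
        row = {"lambda": lam, "mu": mu, "gamma1": g1, "gamma2": g2, "score": mean_score}
        table.append(row)
        if best is None or mean_score > best["score"] - 1e-12:
            best = row
    assert best is not None
    selected = {k: best[k] for k in ("lambda", "mu", "gamma1", "gamma2")}
    return selected, table, folds


# ---------------------------------------------------------------------------
# full model


def fit_multiblock(
    method: str,
    blocks: list[np.ndarray],
    Y: np.ndarray,
    params: MethodParams,
    L1: np.ndarray | None = None,
    L2: np.ndarray | None = None,
    center: bool = True,
) -> LatentComponentSet:
    """Fit ``params.n_modules`` latent components sequentially.

    Penalties are selected once, by cross-validation on the full data,
    before any component is extracted (pass single-value grids to skip
    the search).  Between components each predictor block is deflated
    by its own score in regression mode and the response by the super
    score, so the response residual is orthogonal to every extracted
    super score.
    """
    blocks = [np.asarray(X, dtype=float) for X in blocks]
    Y = np.asarray(Y, dtype=float)
    if center:
        blocks = [center_columns(X) for X in blocks]
        Y = center_columns(Y)

    single = all(
        len(list(g)) == 1
        for g in (params.lambda_grid, params.mu_grid, params.gamma1_grid, params.gamma2_grid)
    )
    if single:
        selected = {
            "lambda": params.lambda_grid[0],
            "mu": params.mu_grid[0],
            "gamma1": params.gamma1_grid[0],
            "gamma2": params.gamma2_grid[0],
        }
        cv_table, folds = [], []
    else:
        selected, cv_table, folds = cross_validate_params(method, blocks, Y, params, L1, L2)

    components: list[PLSComponent] = []
    Xc = [X.copy() for X in blocks]
    Yc = Y.copy()
    for _ in range(params.n_modules):
        comp = _fit_component(
            method,
            Xc,
            Yc,
            selected["lambda"],
            selected["mu"],
            (selected["gamma1"], selected["gamma2"]),
            L1,
            L2,
            params.sparsity_mode,
        )
        components.append(comp)
        # regression-mode deflation: each block by its own score, Y by t
        for i in range(len(Xc)):
            ti = comp.t_list[i]
            tt = float(ti @ ti)
            if tt > _EPS:
                Xc[i] = Xc[i] - np.outer(ti, comp.p_list[i])
        tt = float(comp.t @ comp.t)
        if tt > _EPS:
            Yc = Yc - np.outer(comp.t, comp.t @ Yc) / tt

    return LatentComponentSet(
        components=components,
        method=method,
        params_used=params,
        selected_lambda=float(selected["lambda"]),
        selected_mu=float(selected["mu"]),
        selected_gammas=(float(selected["gamma1"]), float(selected["gamma2"])),
        cv_table=cv_table,
        folds=folds,
    )
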