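"""Optimal-transport primitives: log-domain Sinkhorn and small exact plans.

Squared-Euclidean cost throughout.  The entropic solver runs in the log
domain (stable for small regularisation) and supports warm starting from
previous dual potentials, which the mean-field Langevin loop exploits.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist


class SinkhornError(RuntimeError):
    pass


def sq_cost(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return cdist(np.atleast_2d(x), np.atleast_2d(y), "sqeuclidean")


def sinkhorn_log(
    a: np.ndarray,
    b: np.ndarray,
    C: np.ndarray,
    epsilon: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    raise_on_fail: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entropic OT between histograms ``a`` and ``b`` for cost ``C``.

    Returns ``(plan, f, g)`` where f, g are the converged Schrödinger duals
    (in cost units).  Convergence is measured by the max marginal violation.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    loga = np.log(np.clip(a, 1e-300, None))
    logb = np.log(np.clip(b, 1e-300, None))
    f = np.zeros_like(a) if warm is None else warm[0].copy()
    g = np.zeros_like(b) if warm is None else warm[1].copy()
    if warm is None:
        # epsilon scaling: anneal from a coarse regulariser down to the target
        eps_hot = 0.25 * float(np.median(C)) + epsilon
        while eps_hot > 1.05 * epsilon:
            K = -C / eps_hot
            for _ in range(40):
                M = K + (g / eps_hot)[None, :] + logb[None, :]
                f = -eps_hot * _lse(M, axis=1)
                M = K + (f / eps_hot)[:, None] + loga[:, None]
                g = -eps_hot * _lse(M, axis=0)
            eps_hot = max(epsilon, 0.5 * eps_hot)
    K = -C / epsilon
    for it in range(max_iter):
        # f-update: f_i = -eps * LSE_j[(g_j - C_ij)/eps + log b_j]
        M = K + (g / epsilon)[None, :] + logb[None, :]
        f = -epsilon * _lse(M, axis=1)
        M = K + (f / epsilon)[:, None] + loga[:, None]
        g = -epsilon * _lse(M, axis=0)
        if it % 5 == 0 or it == max_iter - 1:
            logP = K + (f / epsilon)[:, None] + (g / epsilon)[None, :] \
                + loga[:, None] + logb[None, :]
            P = np.exp(logP)
            err = max(np.abs(P.sum(axis=1) - a).max(),
                      np.abs(P.sum(axis=0) - b).max())
            if err < tol:
                return P, f, g
    if raise_on_fail:
        raise SinkhornError(
            f"Sinkhorn failed to reach tol={tol} in {max_iter} iterations "
            f"(eps={epsilon:g}); clouds may be disjoint at this regularisation")
    # best-effort plan with exact row marginals (columns approximately right)
    P = P * (a / np.clip(P.sum(axis=1), 1e-300, None))[:, None]
    return P, f, g


def _lse(M: np.ndarray, axis: int) -> np.ndarray:
    mx = M.max(axis=axis, keepdims=True)
    out = mx.squeeze(axis) + np.log(np.exp(M - mx).sum(axis=axis))
    return out


def round_to_marginals(P: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Project an almost-feasible plan onto the transportation polytope
    (Altschuler-style rounding): scale rows down to a, then columns down to
    b, then add the rank-one residual.  Exact marginals by construction."""
    r = np.minimum(1.0, a / np.clip(P.sum(axis=1), 1e-300, None))
    P = P * r[:, None]
    c = np.minimum(1.0, b / np.clip(P.sum(axis=0), 1e-300, None))
    P = P * c[None, :]
    da = a - P.sum(axis=1)
    db = b - P.sum(axis=0)
    s = da.sum()
    if s > 1e-300:
        P = P + np.outer(da, db) / s
    return P


def exact_plan(a: np.ndarray, b: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Exact optimal transport plan by linear programming (small instances).

    Solves ``min <P, C>`` over the transportation polytope with marginals
    ``a`` and ``b`` (normalised internally).  Suitable up to a few hundred
    atoms per side.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / a.sum()
    b = b / b.sum()
    n, m = C.shape
    # sparse equality constraints: row sums = a, col sums = b (one col-sum
    # row dropped as redundant)
    from scipy import sparse
    ij = np.arange(n * m)
    row_block = sparse.csr_matrix((np.ones(n * m), (ij // m, ij)), shape=(n, n * m))
    col_block = sparse.csr_matrix((np.ones(n * m), (ij % m, ij)), shape=(m, n * m))
    A_eq = sparse.vstack([row_block, col_block[:-1]])
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(C.reshape(-1), A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"exact OT LP failed: {res.message}")
    return res.x.reshape(n, m)


def transport_plan(
    a: np.ndarray,
    b: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    epsilon: float | None = None,
    exact_limit: int = 500,
) -> np.ndarray:
    """Quadratic-cost plan between weighted clouds: exact LP when both sides
    are small, lightly-regularised Sinkhorn otherwise."""
    C = sq_cost(x, y)
    if epsilon is None and max(C.shape) <= exact_limit:
        return exact_plan(a, b, C)
    if epsilon is None:
        epsilon = 0.01 * float(np.median(C)) + 1e-12
    P, _, _ = sinkhorn_log(a / a.sum(), b / b.sum(), C, epsilon, tol=1e-7)
    return P
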