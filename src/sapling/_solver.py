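"""Internal numeric kernel for the sum-condition-constrained binomial MLE.

Works on dense integer-indexed arrays; label bookkeeping lives in
:mod:`sapling.likelihood`.  Trees are passed as parent vectors: ``par[j]``
is the column index of the parent of column ``j``, with ``-1`` at the root.

The optimization is carried out in clone-fraction space.  Writing
``f = M u`` where ``M[i, j] = 1`` iff mutation i is an ancestor of (or equal
to) mutation j, the sum condition ``f_i >= sum of children's f`` together
with ``0 <= f <= 1`` is equivalent to the simple set ``u >= 0``,
``sum(u) <= 1``.  The objective is concave, so the optimum found under
these linear constraints is global.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize

# SLSQP exit statuses accepted as converged.  Status 8 ("positive directional
# derivative for linesearch") is how SLSQP reports that no further progress is
# possible; on this problem class it coincides with optimality to ~1e-7.
_OK_STATUS = (0, 8)


def anc_matrix(par: np.ndarray) -> np.ndarray:
    """Ancestor-or-self indicator matrix M with f = M @ u."""
    n = len(par)
    M = np.zeros((n, n))
    for j in range(n):
        k = j
        while k != -1:
            M[k, j] = 1.0
            k = par[k]
    return M


def children_sums(par: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per column i: sum of F over the children of i (rows = samples)."""
    n = len(par)
    out = np.zeros_like(F, dtype=float)
    for j in range(n):
        p = par[j]
        if p >= 0:
            out[:, p] += F[:, j]
    return out


def naive_f(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Entrywise a/d with the d = 0 -> 0 convention."""
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(D > 0, A / np.where(D > 0, D, 1), 0.0)
    return F


def loglik_terms(A: np.ndarray, D: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood per entry (coefficients omitted, 0*log0 = 0).

    Entries with a > 0 at f = 0, or a < d at f = 1, evaluate to -inf.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    F = np.asarray(F, dtype=float)
    out = np.zeros(np.broadcast(A, F).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(A > 0, A * np.log(F), 0.0)
        t2 = np.where(D - A > 0, (D - A) * np.log1p(-F), 0.0)
    return t1 + t2


def sc_feasible(par: np.ndarray, F: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Boolean per sample: does row of F satisfy the sum condition for par?"""
    slack = F - children_sums(par, F)
    return (slack >= -tol).all(axis=1)


def fit_tree(
    A: np.ndarray,
    D: np.ndarray,
    par: np.ndarray,
    Fhat: Optional[np.ndarray] = None,
    ftol: float = 1e-10,
    f_clamp: float = 1e-9,
    max_iter: int = 10_000,
) -> Tuple[float, np.ndarray, bool, int]:
    """Maximize the binomial log-likelihood subject to the sum condition.

    Returns ``(loglik, F_star, converged, iterations)``.  Samples whose
    naive frequencies already satisfy the sum condition keep them (they are
    the unconstrained optimum); the rest are solved independently.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    if Fhat is None:
        Fhat = naive_f(A, D)
    m, n = A.shape
    F_star = Fhat.copy()
    feas = sc_feasible(par, Fhat)
    converged = True
    iters = 0
    if not feas.all():
        M = anc_matrix(par)
        for p in np.nonzero(~feas)[0]:
            f, u, ok, nit = _fit_sample(A[p], D[p], M, par, Fhat[p], ftol, f_clamp, max_iter)
            F_star[p] = f
            converged &= ok
            iters += nit
    ll = float(loglik_terms(A, D, F_star).sum())
    return ll, F_star, converged, iters


def _fit_sample(
    a: np.ndarray,
    d: np.ndarray,
    M: np.ndarray,
    par: np.ndarray,
    fhat: np.ndarray,
    ftol: float,
    f_clamp: float,
    max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, bool, int]:
    n = len(a)
    lo, hi = f_clamp, 1.0 - f_clamp

    def negll(u: np.ndarray) -> float:
        F = np.clip(M @ u, lo, hi)
        return -(a * np.log(F) + (d - a) * np.log1p(-F)).sum()

    def grad(u: np.ndarray) -> np.ndarray:
        F = np.clip(M @ u, lo, hi)
        return M.T @ (-(a / F - (d - a) / (1.0 - F)))

    # exact clone fractions of the naive frequencies, clipped into the cone
    u0 = fhat - children_sums(par, fhat[None, :])[0]
    u0 = np.clip(u0, 1e-4, None)
    s = u0.sum()
    if s > 1.0:
        u0 *= (1.0 - 1e-9) / s

    cons = [{"type": "ineq", "fun": lambda u: 1.0 - u.sum(), "jac": lambda u: -np.ones(n)}]
    opts = {"ftol": ftol, "maxiter": min(max_iter, 500)}
    res = minimize(negll, u0, jac=grad, method="SLSQP",
                   bounds=[(0.0, 1.0)] * n, constraints=cons, options=opts)
    nit = res.nit
    if res.status not in _OK_STATUS:
        # deterministic retry from a uniform interior point
        res2 = minimize(negll, np.full(n, 1.0 / (n + 1)), jac=grad, method="SLSQP",
                        bounds=[(0.0, 1.0)] * n, constraints=cons, options=opts)
        nit += res2.nit
        if res2.fun < res.fun:
            res = res2
    u = np.clip(res.x, 0.0, None)
    s = u.sum()
    if s > 1.0:
        u /= s
    f = M @ u  # exactly feasible by construction
    ok = res.status in _OK_STATUS
    return f, u, ok, nit


# ---------------------------------------------------------------------------
# closed-form edge bounds used by the brute-force oracle
# ---------------------------------------------------------------------------

def unconstrained_column_loglik(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Per-sample, per-column log-likelihood at the naive frequencies."""
    return loglik_terms(A, D, naive_f(A, D))


def edge_pool_gains(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """gains[i, j] = drop in log-likelihood forced by the single constraint
    f_i >= f_j (i the parent), relative to the unconstrained optimum.

    For one sample the constrained two-column MLE is the naive estimate when
    already ordered, and the pooled proportion (a_i + a_j) / (d_i + d_j) for
    both columns otherwise (pool-adjacent-violators on a two-element chain).
    Summed over samples.  Used as an exact upper bound: for any tree
    containing a vertex-disjoint set E' of edges,
    loglik(T) <= loglik(naive) - sum of gains over E'.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    m, n = A.shape
    Fhat = naive_f(A, D)
    unc = loglik_terms(A, D, Fhat)  # m x n
    gains = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            g = 0.0
            for p in range(m):
                if Fhat[p, i] >= Fhat[p, j]:
                    continue
                dd = D[p, i] + D[p, j]
                pool = (A[p, i] + A[p, j]) / dd if dd > 0 else 0.0
                pooled = (
                    loglik_terms(A[p, i], D[p, i], pool)
                    + loglik_terms(A[p, j], D[p, j], pool)
                )
                g += unc[p, i] + unc[p, j] - float(pooled)
            gains[i, j] = g
    return gains
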