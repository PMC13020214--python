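"""Binomial likelihood of read counts under a tree-constrained frequency matrix.

The scoring kernel of the whole package: for a candidate mutation tree T,
the log-likelihood of read counts (A, D) is the maximum over all frequency
matrices F of

    sum_{p,i} [ a_{p,i} log f_{p,i} + (d_{p,i} - a_{p,i}) log(1 - f_{p,i}) ]

subject to the sum condition (SC): for every sample p and mutation i,
f_{p,i} >= sum of f_{p,j} over the children j of i in T.  Binomial
coefficients are omitted throughout; they are constant in F and cancel in
every likelihood ratio the package uses.  The problem is concave with
linear constraints, so the optimum is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import _solver
from .trees import MutationTree, Node, ReadCountData

__all__ = [
    "FrequencyMatrix",
    "SolverConfig",
    "LikelihoodFit",
    "naive_frequencies",
    "loglik_at",
    "fit_frequencies",
]


@dataclass(frozen=True)
class FrequencyMatrix:
    """Real matrix of mutation frequencies in [0, 1], with labels."""

    samples: List[str]
    mutations: List[Node]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.samples), len(self.mutations)):
            raise ValueError("frequency matrix shape does not match labels")
        if (values < -1e-9).any() or (values > 1 + 1e-9).any():
            raise ValueError("frequencies must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def column(self, mutation: Node) -> np.ndarray:
        return self.values[:, self.mutations.index(mutation)]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs for the constrained maximum-likelihood fit.

    tol      -- relative convergence tolerance on the log-likelihood.
    f_clamp  -- frequencies are clamped to [f_clamp, 1 - f_clamp] inside the
                objective to keep gradients finite; the reported likelihood
                is evaluated at the unclamped feasible optimum.
    max_iter -- iteration cap across solver calls for one fit.
    """

    tol: float = 1e-8
    f_clamp: float = 1e-9
    max_iter: int = 10_000

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0 < self.f_clamp < 0.5:
            raise ValueError("f_clamp must be in (0, 0.5)")


@dataclass
class LikelihoodFit:
    tree: MutationTree
    F_star: FrequencyMatrix
    loglik: float
    converged: bool
    solver_iterations: int = 0


def naive_frequencies(data: ReadCountData) -> FrequencyMatrix:
    """The unconstrained MLE a/d per entry (0 where d = 0)."""
    return FrequencyMatrix(data.samples, list(data.mutations), _solver.naive_f(data.A, data.D))


def loglik_at(data: ReadCountData, F: FrequencyMatrix) -> float:
    """Log-likelihood of the data at a fixed frequency matrix.

    Columns of F may be a subset of the data's mutations; only those columns
    contribute.  Entries with a > 0 at f = 0 (or a < d at f = 1) yield -inf.
    """
    idx = [data.column_index(mut) for mut in F.mutations]
    if F.values.shape[0] != data.m:
        raise ValueError("sample dimension mismatch")
    return float(_solver.loglik_terms(data.A[:, idx], data.D[:, idx], F.values).sum())


def fit_frequencies(
    data: ReadCountData,
    tree: MutationTree,
    cfg: Optional[SolverConfig] = None,
) -> LikelihoodFit:
    """Maximize the binomial log-likelihood over (SC)-feasible frequencies.

    The data are restricted to the columns spanned by the tree before
    solving, so a backbone tree on a mutation subset is scored on exactly
    that subset.  The returned frequencies satisfy the sum condition exactly
    (they are synthesized from nonnegative clone fractions).
    """
    cfg = cfg or SolverConfig()
    cols = [mut for mut in data.mutations if mut in tree]
    if len(cols) != len(tree):
        missing = tree.nodes - set(data.mutations)
        raise KeyError(f"tree nodes missing from data: {sorted(map(repr, missing))}")
    col_idx = {mut: j for j, mut in enumerate(cols)}
    par = np.full(len(cols), -1, dtype=np.int64)
    for child, parent in tree.parent_map.items():
        par[col_idx[child]] = col_idx[parent]
    idx = [data.column_index(mut) for mut in cols]
    A, D = data.A[:, idx], data.D[:, idx]
    ll, F_star, converged, iters = _solver.fit_tree(
        A, D, par, ftol=cfg.tol * 1e-2, f_clamp=cfg.f_clamp, max_iter=cfg.max_iter
    )
    if not converged:
        warnings.warn(
            f"likelihood fit did not converge for tree rooted at {tree.root!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    return LikelihoodFit(
        tree=tree,
        F_star=FrequencyMatrix(data.samples, cols, np.clip(F_star, 0.0, 1.0)),
        loglik=ll,
        converged=converged,
        solver_iterations=iters,
    )
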