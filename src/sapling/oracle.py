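"""Exact brute-force ground truth for small mutation counts.

Enumerates every rooted labeled tree on the full mutation set, scores each
with the constrained binomial likelihood, and retains the rho-solution
space.  Optimal mutation subsets (minimum backbone count at fixed subset
size; maximum subset size under a backbone-count budget) are found by
exhaustive subset enumeration.  This module is deliberately simple -- it is
the ground truth against which the enumeration heuristics are evaluated.

The only sophistication is an *exact* pruning device: relaxing the sum
condition to a vertex-disjoint set of single-edge constraints yields a
closed-form upper bound on every tree's likelihood (binomial pooling per
edge).  Trees are processed in descending bound order and fitting stops as
soon as the bound falls below the rho cutoff, which cannot change the
result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import _solver
from .enumeration import LOG_SLACK
from .likelihood import SolverConfig
from .trees import (
    BackboneForest,
    MutationTree,
    Node,
    ReadCountData,
    canonical_key,
    enumerate_all_rooted_trees,
    project,
)

__all__ = [
    "SolutionSpace",
    "solution_space",
    "project_space",
    "optimal_subset_for_ell",
    "optimal_subset_for_tau",
]

#: default guard on the brute-force enumeration (n^(n-1) trees are fitted)
MAX_BRUTE_FORCE_N = 8


@dataclass
class SolutionSpace:
    """All full trees within a likelihood factor rho of the best tree."""

    rho: float
    mutations: List[Node]
    trees: List[MutationTree]
    logliks: List[float]
    max_loglik: float

    def __len__(self) -> int:
        return len(self.trees)


def _tree_to_par(tree: MutationTree, col_of: Dict[Node, int]) -> np.ndarray:
    par = np.full(len(col_of), -1, dtype=np.int64)
    for child, parent in tree.parent_map.items():
        par[col_of[child]] = col_of[parent]
    return par


def _matching_bound(par: np.ndarray, gains: np.ndarray, base: float) -> float:
    """base minus the total gain of a greedy vertex-disjoint edge matching."""
    edges = [(gains[p, j], p, j) for j, p in enumerate(par) if p >= 0 and gains[p, j] > 0.0]
    if not edges:
        return base
    edges.sort(reverse=True)
    used = set()
    total = 0.0
    for g, p, j in edges:
        if p in used or j in used:
            continue
        used.add(p)
        used.add(j)
        total += g
    return base - total


def solution_space(
    data: ReadCountData,
    rho: float,
    solver: Optional[SolverConfig] = None,
    max_n: int = MAX_BRUTE_FORCE_N,
) -> SolutionSpace:
    """Fit every rooted labeled tree on all n mutations and keep those within
    a factor rho of the maximum likelihood.

    The solver tolerance defaults to a tightened 1e-10 so membership at the
    rho boundary is stable; boundary ties are included.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if data.n > max_n:
        raise ValueError(
            f"n={data.n} exceeds the brute-force guard max_n={max_n}; "
            "pass max_n explicitly to override"
        )
    solver = solver or SolverConfig(tol=1e-10)
    ftol = solver.tol * 1e-2
    cols = list(data.mutations)
    col_of = {mut: j for j, mut in enumerate(cols)}
    A, D = data.A, data.D
    Fhat = _solver.naive_f(A, D)
    base = float(_solver.loglik_terms(A, D, Fhat).sum())
    gains = _solver.edge_pool_gains(A, D)
    log_rho = math.log(rho) if rho > 0 else -math.inf

    # upper bound per tree, then fit in descending bound order
    entries: List[Tuple[float, MutationTree, np.ndarray]] = []
    for tree in enumerate_all_rooted_trees(cols, max_nodes=max(max_n, 9)):
        par = _tree_to_par(tree, col_of)
        entries.append((_matching_bound(par, gains, base), tree, par))
    entries.sort(key=lambda e: -e[0])

    best = -math.inf
    kept: List[Tuple[MutationTree, float]] = []
    for ub, tree, par in entries:
        if ub < best + log_rho - LOG_SLACK:
            break  # bounds are sorted descending: no later tree can qualify
        ll, *_ = _solver.fit_tree(A, D, par, Fhat=Fhat, ftol=ftol,
                                  f_clamp=solver.f_clamp, max_iter=solver.max_iter)
        if ll > best:
            best = ll
            cut = best + log_rho - LOG_SLACK
            kept = [(t, l) for t, l in kept if l >= cut]
        if ll >= best + log_rho - LOG_SLACK:
            kept.append((tree, ll))
    return SolutionSpace(
        rho=rho,
        mutations=cols,
        trees=[t for t, _ in kept],
        logliks=[l for _, l in kept],
        max_loglik=best,
    )


def project_space(space: SolutionSpace, subset: Sequence[Node]) -> List[BackboneForest]:
    """Deduplicated projections of every tree in the space onto ``subset``."""
    S = set(subset)
    seen: Set[str] = set()
    out: List[BackboneForest] = []
    for tree in space.trees:
        f = project(tree, S)
        key = canonical_key(f)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def optimal_subset_for_ell(
    space: SolutionSpace, ell: int
) -> Tuple[List[Node], List[BackboneForest]]:
    """Size-ell mutation subset minimizing the number of distinct backbones.

    Ties are resolved in favor of the lexicographically smallest subset in
    the space's mutation order.
    """
    if not 1 <= ell <= len(space.mutations):
        raise ValueError(f"ell={ell} out of range [1, {len(space.mutations)}]")
    best_S: Optional[Tuple[Node, ...]] = None
    best_proj: Optional[List[BackboneForest]] = None
    for S in combinations(space.mutations, ell):
        proj = project_space(space, S)
        if best_proj is None or len(proj) < len(best_proj):
            best_S, best_proj = S, proj
    return list(best_S), best_proj


def optimal_subset_for_tau(
    space: SolutionSpace, tau: int
) -> Tuple[List[Node], List[BackboneForest]]:
    """Maximum-cardinality subset whose backbone count is at most tau."""
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    n = len(space.mutations)
    for size in range(n, 0, -1):
        for S in combinations(space.mutations, size):
            proj = project_space(space, S)
            if len(proj) <= tau:
                return list(S), proj
    raise AssertionError("unreachable: any singleton has exactly one backbone")
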