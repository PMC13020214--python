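"""Frequency-ordered iterative backbone enumeration and beam search.

The heuristic considers mutations in descending order of their naive
frequency column sums -- mutations near the root of the true tree tend to
have the largest frequencies across samples -- and grows the candidate set
one mutation at a time.  After each insertion round, candidates are scored
by the tree-constrained binomial likelihood on the columns added so far and
either (a) every candidate within a factor rho of the round's maximum
likelihood is retained, or (b) only the top-w candidates are retained
(beam search, used for full-tree inference).
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterator, List, Literal, Optional, Tuple

import numpy as np

from . import _solver
from .expansion import big_expand, small_expand
from .likelihood import SolverConfig
from .trees import MutationTree, Node, ReadCountData, canonical_key

__all__ = [
    "EnumerationConfig",
    "BeamConfig",
    "BackboneResult",
    "mutation_order",
    "fast_backbone_enumeration",
    "backbone_by_tau",
    "beam_enumeration",
]

logger = logging.getLogger(__name__)

# slack applied to the log-domain rho cutoff so exact ties at the optimum
# are never dropped to floating-point noise
LOG_SLACK = 1e-6


@dataclass(frozen=True)
class EnumerationConfig:
    """Parameters of the rho-pruned backbone enumeration.

    Exactly one of ``ell`` (number of mutations) or ``tau`` (backbone-count
    budget) is set per run.
    """

    rho: float = 0.9
    ell: Optional[int] = None
    tau: Optional[int] = None
    expand_mode: Literal["small", "big"] = "small"
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if (self.ell is None) == (self.tau is None):
            raise ValueError("exactly one of ell/tau must be set")
        if self.tau is not None and self.tau < 1:
            raise ValueError("tau must be a positive integer")


@dataclass(frozen=True)
class BeamConfig:
    """Beam-search parameters: width w and optional iteration cap ell."""

    width: int = 1
    ell: Optional[int] = None  # defaults to all n mutations
    expand_mode: Literal["small", "big"] = "small"
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("beam width must be >= 1")


@dataclass
class BackboneResult:
    """Mutation subset S with the deduplicated tree set spanning it."""

    S: List[Node]
    trees: List[MutationTree]
    logliks: List[float]
    rho: Optional[float]
    ell_used: int
    history: List[int]  # |T_k| for k = 1..K computed

    def max_loglik(self) -> float:
        return max(self.logliks)


def mutation_order(data: ReadCountData) -> List[Node]:
    """Mutations in descending order of naive-frequency column sums.

    Ties are broken by input column order (stable sort).
    """
    sums = _solver.naive_f(data.A, data.D).sum(axis=0)
    order = np.argsort(-sums, kind="stable")
    return [data.mutations[j] for j in order]


def _expand_fn(mode: str):
    if mode == "small":
        return small_expand
    if mode == "big":
        return big_expand
    raise ValueError(f"unknown expand mode {mode!r}")


def _run(
    data: ReadCountData,
    expand_mode: str,
    solver: SolverConfig,
    max_ell: int,
    retain,
) -> Iterator[Tuple[int, List[Node], List[MutationTree], List[float]]]:
    """Drive the iterative enumeration, yielding the retained set after
    every round.  ``retain(trees, logliks) -> (trees, logliks)`` implements
    the pruning policy (rho cutoff or top-w beam)."""
    order = mutation_order(data)
    max_ell = min(max_ell, len(order))
    expand = _expand_fn(expand_mode)
    ftol = solver.tol * 1e-2

    first = MutationTree._from_validated({}, order[0], {order[0]})
    cols = [order[0]]
    idx = [data.column_index(order[0])]
    ll0, *_ = _solver.fit_tree(data.A[:, idx], data.D[:, idx], np.array([-1]), ftol=ftol,
                               f_clamp=solver.f_clamp, max_iter=solver.max_iter)
    retained, logliks = [first], [ll0]
    yield 1, list(cols), retained, logliks

    for k in range(2, max_ell + 1):
        t_start = time.perf_counter()
        new_mut = order[k - 1]
        cols.append(new_mut)
        idx.append(data.column_index(new_mut))
        A, D = data.A[:, idx], data.D[:, idx]
        Fhat = _solver.naive_f(A, D)
        col_of = {mut: j for j, mut in enumerate(cols)}

        seen = set()
        cand_trees: List[MutationTree] = []
        cand_lls: List[float] = []
        for t in retained:
            for t2 in expand(t, new_mut):
                key = canonical_key(t2)
                if key in seen:
                    continue
                seen.add(key)
                par = np.full(k, -1, dtype=np.int64)
                for child, parent in t2.parent_map.items():
                    par[col_of[child]] = col_of[parent]
                ll, *_ = _solver.fit_tree(A, D, par, Fhat=Fhat, ftol=ftol,
                                          f_clamp=solver.f_clamp, max_iter=solver.max_iter)
                cand_trees.append(t2)
                cand_lls.append(ll)
        retained, logliks = retain(cand_trees, cand_lls)
        logger.info(
            "iteration %d: %d candidates, %d retained (%.3fs)",
            k, len(cand_trees), len(retained), time.perf_counter() - t_start,
        )
        yield k, list(cols), retained, logliks


def _rho_retain(rho: float):
    cutoff_shift = math.log(rho) if rho > 0 else -math.inf

    def retain(trees: List[MutationTree], lls: List[float]):
        best = max(lls)
        cut = best + cutoff_shift - LOG_SLACK
        kept = [(t, ll) for t, ll in zip(trees, lls) if ll >= cut]
        return [t for t, _ in kept], [ll for _, ll in kept]

    return retain


def fast_backbone_enumeration(data: ReadCountData, cfg: EnumerationConfig) -> BackboneResult:
    """Grow backbone trees over the first ``ell`` mutations of the frequency
    order, retaining after each round every candidate within a factor
    ``rho`` of the round's maximum likelihood."""
    if cfg.ell is None:
        raise ValueError("fast_backbone_enumeration requires cfg.ell; use backbone_by_tau for tau")
    if not 1 <= cfg.ell <= data.n:
        raise ValueError(f"ell={cfg.ell} out of range [1, {data.n}]")
    history: List[int] = []
    result = None
    for k, S, trees, lls in _run(data, cfg.expand_mode, cfg.solver, cfg.ell, _rho_retain(cfg.rho)):
        history.append(len(trees))
        result = (S, trees, lls)
    S, trees, lls = result
    return BackboneResult(S=S, trees=trees, logliks=lls, rho=cfg.rho,
                          ell_used=len(S), history=history)


def backbone_by_tau(data: ReadCountData, cfg: EnumerationConfig) -> BackboneResult:
    """Sweep ell upward until the backbone set first exceeds ``tau`` trees,
    returning the last set within budget (all n mutations if never exceeded).

    A single incremental pass: the enumeration is deterministic per prefix,
    so the sweep reuses each round instead of restarting.
    """
    if cfg.tau is None:
        raise ValueError("backbone_by_tau requires cfg.tau")
    history: List[int] = []
    last_ok = None
    for k, S, trees, lls in _run(data, cfg.expand_mode, cfg.solver, data.n, _rho_retain(cfg.rho)):
        history.append(len(trees))
        if len(trees) > cfg.tau:
            break
        last_ok = (S, trees, lls)
    S, trees, lls = last_ok  # k = 1 always has exactly one tree <= tau
    return BackboneResult(S=S, trees=trees, logliks=lls, rho=cfg.rho,
                          ell_used=len(S), history=history)


def beam_enumeration(data: ReadCountData, cfg: BeamConfig) -> BackboneResult:
    """Full-tree inference: same iteration as the backbone enumeration but
    retaining the top-w candidates by likelihood at every round.

    Ties are broken by canonical key, ascending, so results are
    deterministic.  The final trees are sorted by likelihood descending.
    """
    max_ell = cfg.ell if cfg.ell is not None else data.n
    if not 1 <= max_ell <= data.n:
        raise ValueError(f"ell={max_ell} out of range [1, {data.n}]")

    def retain(trees: List[MutationTree], lls: List[float]):
        ranked = sorted(zip(trees, lls), key=lambda p: (-p[1], canonical_key(p[0])))
        ranked = ranked[: cfg.width]
        return [t for t, _ in ranked], [ll for _, ll in ranked]

    history: List[int] = []
    result = None
    for k, S, trees, lls in _run(data, cfg.expand_mode, cfg.solver, max_ell, retain):
        history.append(len(trees))
        result = (S, trees, lls)
    S, trees, lls = result
    ranked = sorted(zip(trees, lls), key=lambda p: (-p[1], canonical_key(p[0])))
    return BackboneResult(S=S, trees=[t for t, _ in ranked], logliks=[ll for _, ll in ranked],
                          rho=None, ell_used=len(S), history=history)
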