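"""Synthetic bulk-sequencing instances with known ground truth.

The generative model: a uniformly random rooted node-labeled tree (Pruefer
sequence plus uniform root choice), per-sample clonal fractions from a
symmetric Dirichlet, mutation frequencies as subtree sums of clonal
fractions (so the sum condition holds exactly and the root frequency is 1),
sequencing depths Poisson with mean lambda = 100, and variant reads
binomial(depth, frequency).  The Dirichlet concentration alpha defaults to
1 (uniform on the simplex) and is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import _solver
from .likelihood import FrequencyMatrix
from .trees import MutationTree, Node, ReadCountData

__all__ = [
    "SimulationConfig",
    "SimulationInstance",
    "random_tree",
    "frequencies_from_fractions",
    "simulate_instance",
]


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    m: int
    depth_mean: float = 100.0
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass
class SimulationInstance:
    truth_tree: MutationTree
    U: np.ndarray  # m x n clonal fractions, rows sum to 1
    F: FrequencyMatrix
    data: ReadCountData
    config: SimulationConfig


def random_tree(n: int, rng: np.random.Generator, labels: Optional[List[Node]] = None) -> MutationTree:
    """Uniform draw over the n^(n-1) rooted labeled trees.

    A uniform Pruefer sequence gives a uniform unrooted labeled tree; the
    root is then chosen uniformly, and the two choices are independent, so
    every rooted tree has probability n^-(n-1).
    """
    if labels is None:
        labels = list(range(n))
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    if n == 1:
        return MutationTree({}, nodes=labels)
    from .trees import _decode_pruefer

    seq = [int(v) for v in rng.integers(0, n, size=max(n - 2, 0))]
    edges = _decode_pruefer(seq, n)
    root = int(rng.integers(0, n))
    adj: List[List[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent = {}
    stack = [root]
    seen = [False] * n
    seen[root] = True
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if not seen[w]:
                seen[w] = True
                parent[labels[w]] = labels[v]
                stack.append(w)
    return MutationTree(parent, nodes=labels)


def frequencies_from_fractions(tree: MutationTree, U: np.ndarray,
                               mutations: Optional[List[Node]] = None,
                               samples: Optional[List[str]] = None) -> FrequencyMatrix:
    """Frequencies as subtree sums of clonal fractions: f_{p,i} is the total
    fraction of clones in sample p whose mutation set contains i.

    The result satisfies the sum condition with equality at every node and
    has frequency exactly 1 at the root.
    """
    U = np.asarray(U, dtype=float)
    if mutations is None:
        mutations = sorted(tree.nodes, key=lambda v: (type(v).__name__, repr(v)))
    if U.shape[1] != len(mutations):
        raise ValueError("U column count does not match mutation count")
    if not np.allclose(U.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("clonal-fraction rows must sum to 1")
    col_of = {mut: j for j, mut in enumerate(mutations)}
    par = np.full(len(mutations), -1, dtype=np.int64)
    for child, parent in tree.parent_map.items():
        par[col_of[child]] = col_of[parent]
    M = _solver.anc_matrix(par)
    F = U @ M.T
    if samples is None:
        samples = [f"sample_{p}" for p in range(U.shape[0])]
    return FrequencyMatrix(samples, list(mutations), np.clip(F, 0.0, 1.0))


def simulate_instance(cfg: SimulationConfig) -> SimulationInstance:
    """Generate one instance, fully reproducible from cfg.seed.

    The RNG is threaded through tree, clonal fractions, depths, and variant
    reads in that fixed order, so a seed pins the entire instance.
    """
    rng = np.random.default_rng(cfg.seed)
    labels: List[Node] = list(range(cfg.n))
    tree = random_tree(cfg.n, rng, labels=labels)
    U = rng.dirichlet(np.full(cfg.n, cfg.dirichlet_alpha), size=cfg.m)
    F = frequencies_from_fractions(tree, U, mutations=labels)
    D = rng.poisson(cfg.depth_mean, size=(cfg.m, cfg.n))
    A = rng.binomial(D, F.values)  # D = 0 entries force A = 0
    data = ReadCountData(F.samples, labels, A, D)
    return SimulationInstance(truth_tree=tree, U=U, F=F, data=data, config=cfg)
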