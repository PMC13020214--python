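"""Distances between clone trees on the same mutation set.

Parent-child (PC) and ancestor-descendant (AD) distances are Jaccard
distances between directed edge sets and between transitive closures,
respectively.  CASet and DISC average Jaccard distances of common-ancestor
sets (over unordered mutation pairs) and of distinctly-inherited ancestor
sets (over ordered pairs); ancestor sets are reflexive (a mutation is its
own ancestor) and the Jaccard distance of two empty sets is defined as 0.
All four metrics are symmetric, lie in [0, 1], and vanish exactly on
identical trees.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Dict, FrozenSet, List, Sequence, Set, Union

from .oracle import SolutionSpace, project_space
from .trees import BackboneForest, MutationTree, Node, canonical_key, transitive_closure

__all__ = [
    "pc_distance",
    "ad_distance",
    "caset_distance",
    "disc_distance",
    "backbone_recall",
]

TreeLike = Union[MutationTree, BackboneForest]


def _check_same_nodes(t1: TreeLike, t2: TreeLike) -> None:
    if t1.nodes != t2.nodes:
        raise ValueError("trees must be on the same mutation set")


def _jaccard_distance(x: Set, y: Set) -> float:
    union = x | y
    if not union:
        return 0.0
    return len(x ^ y) / len(union)


def pc_distance(t1: TreeLike, t2: TreeLike) -> float:
    """Jaccard distance of the directed (parent, child) edge sets."""
    _check_same_nodes(t1, t2)
    return _jaccard_distance(set(t1.edges()), set(t2.edges()))


def ad_distance(t1: TreeLike, t2: TreeLike) -> float:
    """Jaccard distance of the transitive closures (strict ancestor pairs)."""
    _check_same_nodes(t1, t2)
    return _jaccard_distance(transitive_closure(t1), transitive_closure(t2))


def _reflexive_ancestor_sets(tree: MutationTree) -> Dict[Node, FrozenSet[Node]]:
    pmap = tree.parent_map
    anc: Dict[Node, FrozenSet[Node]] = {}

    def get(v: Node) -> FrozenSet[Node]:
        if v not in anc:
            p = pmap.get(v)
            anc[v] = frozenset({v}) if p is None else get(p) | {v}
        return anc[v]

    for v in tree.nodes:
        get(v)
    return anc


def _require_tree(t: TreeLike, name: str) -> MutationTree:
    if isinstance(t, BackboneForest):
        if not t.is_tree():
            raise ValueError(f"{name}: CASet/DISC are defined for single-rooted trees only")
        return t.to_tree()
    return t


def caset_distance(t1: TreeLike, t2: TreeLike) -> float:
    """Mean over unordered mutation pairs of the Jaccard distance between
    their common-ancestor sets."""
    t1 = _require_tree(t1, "t1")
    t2 = _require_tree(t2, "t2")
    _check_same_nodes(t1, t2)
    if len(t1) < 2:
        raise ValueError("CASet requires at least two mutations")
    a1 = _reflexive_ancestor_sets(t1)
    a2 = _reflexive_ancestor_sets(t2)
    total = 0.0
    npairs = 0
    for i, j in combinations(sorted(t1.nodes, key=repr), 2):
        total += _jaccard_distance(set(a1[i] & a1[j]), set(a2[i] & a2[j]))
        npairs += 1
    return total / npairs


def disc_distance(t1: TreeLike, t2: TreeLike) -> float:
    """Mean over ordered mutation pairs (i, j) of the Jaccard distance
    between the distinctly-inherited sets anc(i) minus anc(j)."""
    t1 = _require_tree(t1, "t1")
    t2 = _require_tree(t2, "t2")
    _check_same_nodes(t1, t2)
    if len(t1) < 2:
        raise ValueError("DISC requires at least two mutations")
    a1 = _reflexive_ancestor_sets(t1)
    a2 = _reflexive_ancestor_sets(t2)
    total = 0.0
    npairs = 0
    for i, j in permutations(sorted(t1.nodes, key=repr), 2):
        total += _jaccard_distance(set(a1[i] - a1[j]), set(a2[i] - a2[j]))
        npairs += 1
    return total / npairs


def backbone_recall(
    inferred: Sequence[TreeLike],
    truth_space: SolutionSpace,
    subset: Sequence[Node],
) -> float:
    """Fraction of the ground-truth projected backbones that the inferred
    set recovers (matching by canonical key)."""
    if not inferred:
        raise ValueError("inferred tree set must be non-empty")
    truth = {canonical_key(f) for f in project_space(truth_space, subset)}
    got = {canonical_key(t) for t in inferred}
    return len(got & truth) / len(truth)
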