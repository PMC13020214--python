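"""Candidate-tree generation: insert one new mutation into an existing tree.

Two expansion rules are provided.  The exhaustive rule places the new
mutation below any node and distributes any subset of that node's children
under it (exponentially many candidates per node); the pruned rule only
considers new-root, new-leaf, and single-edge-split placements, giving a
linear number of candidates.  Output order is deterministic so downstream
tie-breaking is reproducible.
"""

from __future__ import annotations

from typing import Dict, List

from .trees import MutationTree, Node, _label_sort_key, canonical_key

__all__ = ["big_expand", "small_expand"]


def _dedupe(trees: List[MutationTree]) -> List[MutationTree]:
    seen = set()
    out = []
    for t in trees:
        k = canonical_key(t)
        if k not in seen:
            seen.add(k)
            out.append(t)
    return out


def _with_new_root(tree: MutationTree, i: Node) -> MutationTree:
    pmap = tree.parent_map
    pmap[tree.root] = i
    return MutationTree._from_validated(pmap, i, tree.nodes | {i})


def big_expand(tree: MutationTree, i: Node) -> List[MutationTree]:
    """All trees obtained by inserting ``i``: as new root, or as a child of
    any node j adopting any subset of j's children.

    Produces 1 + sum over nodes j of 2^|children(j)| trees, all distinct.
    """
    if i in tree:
        raise ValueError(f"node {i!r} already in tree")
    nodes = tree.nodes | {i}
    out = [_with_new_root(tree, i)]
    for j in sorted(tree.nodes, key=_label_sort_key):
        kids = tree.children(j)  # already label-sorted
        for mask in range(1 << len(kids)):  # binary-counter order over subsets
            pmap = tree.parent_map
            pmap[i] = j
            for b, c in enumerate(kids):
                if mask >> b & 1:
                    pmap[c] = i
            out.append(MutationTree._from_validated(pmap, tree.root, nodes))
    return _dedupe(out)


def small_expand(tree: MutationTree, i: Node) -> List[MutationTree]:
    """Pruned insertion of ``i``: new root, new leaf under any node, or
    splitting any existing edge.  Produces exactly 2 |V(T)| trees, a subset
    of ``big_expand(tree, i)``.
    """
    if i in tree:
        raise ValueError(f"node {i!r} already in tree")
    nodes = tree.nodes | {i}
    out = [_with_new_root(tree, i)]
    for j in sorted(tree.nodes, key=_label_sort_key):
        pmap = tree.parent_map
        pmap[i] = j
        out.append(MutationTree._from_validated(pmap, tree.root, nodes))
    for j in sorted(tree.nodes - {tree.root}, key=_label_sort_key):
        pmap = tree.parent_map
        pmap[i] = pmap[j]
        pmap[j] = i
        out.append(MutationTree._from_validated(pmap, tree.root, nodes))
    return _dedupe(out)
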