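"""Rooted node-labeled trees, backbone projection, and exhaustive enumeration.

Clone trees (mutation trees) differ from species phylogenies in that *every*
node carries a mutation label, not just the leaves.  A backbone tree on a
subset ``S`` of mutations is obtained by contracting all nodes outside ``S``
while preserving every ancestral relation among the members of ``S``.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, Hashable, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

Node = Hashable

__all__ = [
    "TreeValidationError",
    "CycleError",
    "RootCountError",
    "UnknownNodeError",
    "MutationTree",
    "BackboneForest",
    "ReadCountData",
    "make_tree",
    "is_ancestor",
    "project",
    "canonical_key",
    "enumerate_all_rooted_trees",
    "transitive_closure",
]


class TreeValidationError(ValueError):
    """Base class for invalid tree construction."""


class CycleError(TreeValidationError):
    """The parent map contains a directed cycle."""


class RootCountError(TreeValidationError):
    """The parent map has zero roots or more than one root."""


class UnknownNodeError(TreeValidationError):
    """A referenced node is not part of the tree."""


def _label_sort_key(v: Node) -> Tuple[str, str]:
    # repr() distinguishes e.g. the int 1 from the string "1"
    return (type(v).__name__, repr(v))


class MutationTree:
    """A rooted tree whose nodes are mutation labels.

    The tree is stored as a parent map; the root is the unique node without
    a parent.  Instances are immutable once constructed.
    """

    __slots__ = ("_parent", "_root", "_children", "_nodes")

    def __init__(self, parent: Mapping[Node, Node], nodes: Optional[Iterable[Node]] = None):
        tree = make_tree(parent, nodes=nodes)
        self._parent = tree._parent
        self._root = tree._root
        self._children = tree._children
        self._nodes = tree._nodes

    @classmethod
    def _from_validated(cls, parent: Dict[Node, Node], root: Node, nodes: Set[Node]) -> "MutationTree":
        self = object.__new__(cls)
        self._parent = parent
        self._root = root
        self._nodes = nodes
        self._children = None
        return self

    # -- basic accessors -------------------------------------------------
    @property
    def root(self) -> Node:
        return self._root

    @property
    def nodes(self) -> Set[Node]:
        return set(self._nodes)

    @property
    def parent_map(self) -> Dict[Node, Node]:
        return dict(self._parent)

    def parent(self, v: Node) -> Optional[Node]:
        """Parent of ``v``; ``None`` for the root."""
        if v not in self._nodes:
            raise UnknownNodeError(f"node {v!r} not in tree")
        return self._parent.get(v)

    def _child_map(self) -> Dict[Node, List[Node]]:
        if self._children is None:
            ch: Dict[Node, List[Node]] = {v: [] for v in self._nodes}
            for c, p in self._parent.items():
                ch[p].append(c)
            for v in ch:
                ch[v].sort(key=_label_sort_key)
            self._children = ch
        return self._children

    def children(self, v: Node) -> List[Node]:
        if v not in self._nodes:
            raise UnknownNodeError(f"node {v!r} not in tree")
        return list(self._child_map()[v])

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, v: Node) -> bool:
        return v in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, (MutationTree, BackboneForest)):
            return NotImplemented
        return canonical_key(self) == canonical_key(other)

    def __hash__(self) -> int:
        return hash(canonical_key(self))

    def __repr__(self) -> str:
        return f"MutationTree(root={self._root!r}, n={len(self._nodes)})"

    # -- export -----------------------------------------------------------
    def edges(self) -> List[Tuple[Node, Node]]:
        """Directed (parent, child) edges."""
        return [(p, c) for c, p in self._parent.items()]

    def to_json_obj(self) -> Dict[str, object]:
        return {
            "root": self._root,
            "parent": {str(c): p for c, p in self._parent.items()},
        }


class BackboneForest:
    """A forest on a mutation subset: parent map with zero or more roots.

    Projections of a tree onto a subset that excludes a common ancestor
    naturally yield several roots; enumeration algorithms only ever produce
    single-rooted trees.
    """

    __slots__ = ("_parent", "_roots", "_nodes")

    def __init__(self, parent: Mapping[Node, Node], nodes: Iterable[Node]):
        nodes = set(nodes)
        parent = dict(parent)
        for c, p in parent.items():
            if c not in nodes or p not in nodes:
                raise UnknownNodeError(f"edge ({p!r} -> {c!r}) references unknown node")
        _check_acyclic(parent)
        self._parent = parent
        self._nodes = nodes
        self._roots = sorted((v for v in nodes if v not in parent), key=_label_sort_key)

    @property
    def nodes(self) -> Set[Node]:
        return set(self._nodes)

    @property
    def roots(self) -> List[Node]:
        return list(self._roots)

    @property
    def parent_map(self) -> Dict[Node, Node]:
        return dict(self._parent)

    def parent(self, v: Node) -> Optional[Node]:
        if v not in self._nodes:
            raise UnknownNodeError(f"node {v!r} not in forest")
        return self._parent.get(v)

    def is_tree(self) -> bool:
        return len(self._roots) == 1

    def to_tree(self) -> MutationTree:
        if not self.is_tree():
            raise RootCountError(f"forest has {len(self._roots)} roots; cannot convert to tree")
        return MutationTree._from_validated(dict(self._parent), self._roots[0], set(self._nodes))

    def edges(self) -> List[Tuple[Node, Node]]:
        return [(p, c) for c, p in self._parent.items()]

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, v: Node) -> bool:
        return v in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, (MutationTree, BackboneForest)):
            return NotImplemented
        return canonical_key(self) == canonical_key(other)

    def __hash__(self) -> int:
        return hash(canonical_key(self))

    def __repr__(self) -> str:
        return f"BackboneForest(roots={self._roots!r}, n={len(self._nodes)})"


class ReadCountData:
    """Variant (A) and total (D) read-count matrices over samples x mutations."""

    __slots__ = ("samples", "mutations", "A", "D", "_col")

    def __init__(
        self,
        samples: Sequence[str],
        mutations: Sequence[Node],
        A: np.ndarray,
        D: np.ndarray,
    ):
        samples = list(samples)
        mutations = list(mutations)
        A = np.asarray(A, dtype=np.int64)
        D = np.asarray(D, dtype=np.int64)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample labels")
        if len(set(mutations)) != len(mutations):
            raise ValueError("duplicate mutation labels")
        if A.shape != (len(samples), len(mutations)) or D.shape != A.shape:
            raise ValueError(
                f"matrix shapes {A.shape}, {D.shape} do not match "
                f"{len(samples)} samples x {len(mutations)} mutations"
            )
        if (A < 0).any() or (D < 0).any():
            raise ValueError("read counts must be nonnegative")
        if (A > D).any():
            p, i = np.argwhere(A > D)[0]
            raise ValueError(
                f"variant reads exceed total reads at sample {samples[p]!r}, "
                f"mutation {mutations[i]!r}"
            )
        self.samples = samples
        self.mutations = mutations
        self.A = A
        self.D = D
        self._col = {mut: j for j, mut in enumerate(mutations)}

    @property
    def m(self) -> int:
        return len(self.samples)

    @property
    def n(self) -> int:
        return len(self.mutations)

    def column_index(self, mutation: Node) -> int:
        try:
            return self._col[mutation]
        except KeyError:
            raise KeyError(f"unknown mutation {mutation!r}") from None

    def subset(self, mutations: Sequence[Node]) -> "ReadCountData":
        """Data restricted to the given mutation columns, in the given order."""
        idx = [self.column_index(mut) for mut in mutations]
        return ReadCountData(self.samples, list(mutations), self.A[:, idx], self.D[:, idx])

    def __repr__(self) -> str:
        return f"ReadCountData(m={self.m}, n={self.n})"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _check_acyclic(parent: Mapping[Node, Node]) -> None:
    state: Dict[Node, int] = {}  # 1 = in progress, 2 = done
    for start in parent:
        v = start
        path = []
        while v in parent and state.get(v, 0) == 0:
            state[v] = 1
            path.append(v)
            v = parent[v]
            if state.get(v, 0) == 1:
                raise CycleError(f"cycle through node {v!r}")
        for u in path:
            state[u] = 2


def make_tree(parent: Mapping[Node, Node], nodes: Optional[Iterable[Node]] = None) -> MutationTree:
    """Validate a parent map and return the resulting rooted tree.

    ``nodes`` only needs to be supplied for a single-node tree (whose parent
    map is empty); otherwise the node set is inferred from the map.
    """
    parent = dict(parent)
    node_set: Set[Node] = set(parent) | set(parent.values())
    if nodes is not None:
        nodes = set(nodes)
        unknown = set(parent) | set(parent.values())
        if not unknown <= nodes:
            raise UnknownNodeError(
                f"parent map references nodes {sorted(unknown - nodes, key=_label_sort_key)!r} "
                "outside the declared node set"
            )
        node_set = nodes
    if not node_set:
        raise RootCountError("empty tree: no nodes given")
    _check_acyclic(parent)
    roots = [v for v in node_set if v not in parent]
    if len(roots) != 1:
        raise RootCountError(f"expected exactly one root, found {len(roots)}")
    return MutationTree._from_validated(parent, roots[0], node_set)


def is_ancestor(tree: MutationTree, u: Node, v: Node) -> bool:
    """True iff ``u`` lies on the root-to-``v`` path (reflexive)."""
    if u not in tree or v not in tree:
        missing = u if u not in tree else v
        raise UnknownNodeError(f"node {missing!r} not in tree")
    pmap = tree._parent
    w: Optional[Node] = v
    while w is not None:
        if w == u:
            return True
        w = pmap.get(w)
    return False


def project(tree: MutationTree, subset: Iterable[Node]) -> BackboneForest:
    """Backbone of ``tree`` on ``subset``: contract all nodes outside the subset.

    The parent of ``v`` in the projection is its nearest strict ancestor that
    belongs to the subset; ancestral relations among subset members are
    preserved exactly.  The result may have several roots when the subset
    excludes a common ancestor.
    """
    S = set(subset)
    if not S <= tree.nodes:
        raise UnknownNodeError(
            f"subset contains nodes not in tree: {sorted(S - tree.nodes, key=_label_sort_key)!r}"
        )
    pmap = tree._parent
    out: Dict[Node, Node] = {}
    for v in S:
        w = pmap.get(v)
        while w is not None and w not in S:
            w = pmap.get(w)
        if w is not None:
            out[v] = w
    return BackboneForest(out, S)


def canonical_key(obj: "MutationTree | BackboneForest") -> str:
    """Deterministic token; equal iff node sets and parent maps coincide."""
    if isinstance(obj, MutationTree):
        parent = obj._parent
        roots = [obj._root]
        nodes = obj._nodes
    elif isinstance(obj, BackboneForest):
        parent = obj._parent
        roots = obj._roots
        nodes = obj._nodes
    else:
        raise TypeError(f"cannot compute canonical key of {type(obj).__name__}")
    root_part = ",".join(repr(r) for r in sorted(roots, key=_label_sort_key))
    edge_part = ";".join(
        f"{repr(c)}<{repr(parent[c])}"
        for c in sorted(parent, key=_label_sort_key)
    )
    assert set(parent) | set(roots) == set(nodes)
    return f"r[{root_part}]|{edge_part}"


def _decode_pruefer(seq: Sequence[int], n: int) -> List[Tuple[int, int]]:
    """Undirected edges of the labeled tree on 0..n-1 encoded by ``seq``."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges: List[Tuple[int, int]] = []
    for v in seq:
        # smallest remaining leaf; degree 0 marks consumed nodes
        leaf = degree.index(1)
        edges.append((leaf, v))
        degree[leaf] = 0
        degree[v] -= 1
    a = degree.index(1)
    b = degree.index(1, a + 1)
    edges.append((a, b))
    return edges


def enumerate_all_rooted_trees(
    labels: Sequence[Node], max_nodes: int = 9
) -> Iterator[MutationTree]:
    """Stream every rooted labeled tree on ``labels`` exactly once.

    There are n^(n-1) such trees (Cayley's count of labeled trees times the
    n root choices).  Unrooted topologies are enumerated via Pruefer
    sequences and each is rooted at every node in turn.  The stream is
    deterministic: Pruefer sequences in lexicographic order, roots in label
    index order.  ``max_nodes`` guards against accidental combinatorial
    explosions; n = 8 (about 2.1 million trees) is routinely enumerable.
    """
    labels = list(labels)
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")
    if n > max_nodes:
        raise ValueError(
            f"n={n} exceeds max_nodes={max_nodes}; pass a larger max_nodes explicitly"
        )
    if n == 0:
        return
    if n == 1:
        yield MutationTree._from_validated({}, labels[0], {labels[0]})
        return
    nodeset = set(labels)
    for seq in product(range(n), repeat=n - 2):
        edges = _decode_pruefer(seq, n)
        adj: List[List[int]] = [[] for _ in range(n)]
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        for root in range(n):
            parent: Dict[Node, Node] = {}
            stack = [root]
            seen = [False] * n
            seen[root] = True
            while stack:
                v = stack.pop()
                lv = labels[v]
                for w in adj[v]:
                    if not seen[w]:
                        seen[w] = True
                        parent[labels[w]] = lv
                        stack.append(w)
            yield MutationTree._from_validated(parent, labels[root], nodeset)


def transitive_closure(obj: "MutationTree | BackboneForest") -> Set[Tuple[Node, Node]]:
    """All ordered pairs (u, v) with u a *strict* ancestor of v."""
    parent = obj.parent_map
    out: Set[Tuple[Node, Node]] = set()
    for v in obj.nodes:
        w = parent.get(v)
        while w is not None:
            out.add((w, v))
            w = parent.get(w)
    return out
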