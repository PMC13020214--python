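"""Readers and writers: read counts, cluster aggregation, result JSON, DOT.

Read-count input comes either as a long-format TSV with columns
``mutation_id``, ``sample_id``, ``var_reads``, ``total_reads`` (one row per
cell; missing cells are an error, not zero) or as a pair of wide CSV
matrices (samples as rows, mutations as columns) for variant and total
reads with identical headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .enumeration import BackboneResult
from .trees import BackboneForest, MutationTree, Node, ReadCountData, make_tree

__all__ = [
    "read_counts",
    "read_counts_long",
    "read_counts_wide",
    "read_cluster_map",
    "aggregate_clusters",
    "write_result",
    "read_result",
    "tree_to_dot",
    "write_tree_edges",
    "read_tree_edges",
]

LONG_COLUMNS = ["mutation_id", "sample_id", "var_reads", "total_reads"]


def read_counts_long(path: Union[str, Path]) -> ReadCountData:
    """Long-format TSV: one (mutation, sample) cell per row, all cells present."""
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "sample_id": str})
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["mutation_id", "sample_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate cell for mutation {row['mutation_id']!r}, "
            f"sample {row['sample_id']!r}"
        )
    mutations = list(dict.fromkeys(df["mutation_id"]))
    samples = list(dict.fromkeys(df["sample_id"]))
    wide_a = df.pivot(index="sample_id", columns="mutation_id", values="var_reads")
    wide_d = df.pivot(index="sample_id", columns="mutation_id", values="total_reads")
    if wide_a.isna().any().any():
        sample = wide_a.isna().stack()
        sample = sample[sample].index[0]
        raise ValueError(f"{path}: missing cell for sample {sample[0]!r}, mutation {sample[1]!r}")
    A = wide_a.loc[samples, mutations].to_numpy()
    D = wide_d.loc[samples, mutations].to_numpy()
    _validate_counts(A, D, samples, mutations, str(path))
    return ReadCountData(samples, mutations, A, D)


def read_counts_wide(var_path: Union[str, Path], total_path: Union[str, Path]) -> ReadCountData:
    """Wide CSVs: first column sample id, remaining columns mutations."""
    va = pd.read_csv(var_path, index_col=0)
    to = pd.read_csv(total_path, index_col=0)
    if list(va.columns) != list(to.columns) or list(va.index) != list(to.index):
        raise ValueError(
            f"{var_path} and {total_path}: sample/mutation headers do not match"
        )
    if va.isna().any().any() or to.isna().any().any():
        raise ValueError(f"{var_path}/{total_path}: ragged matrix (missing cells)")
    samples = [str(s) for s in va.index]
    mutations = [str(c) for c in va.columns]
    A, D = va.to_numpy(), to.to_numpy()
    _validate_counts(A, D, samples, mutations, str(var_path))
    return ReadCountData(samples, mutations, A, D)


def read_counts(
    path: Union[str, Path, Tuple[Union[str, Path], Union[str, Path]]],
    format: str = "long_tsv",
) -> ReadCountData:
    if format == "long_tsv":
        return read_counts_long(path)  # type: ignore[arg-type]
    if format == "wide_csv":
        var_path, total_path = path  # type: ignore[misc]
        return read_counts_wide(var_path, total_path)
    raise ValueError(f"unknown format {format!r}")


def _validate_counts(A, D, samples, mutations, source: str) -> None:
    A = np.asarray(A)
    D = np.asarray(D)
    if (A < 0).any() or (D < 0).any():
        p, i = np.argwhere((A < 0) | (D < 0))[0]
        raise ValueError(
            f"{source}: negative count at sample {samples[p]!r}, mutation {mutations[i]!r}"
        )
    if (A > D).any():
        p, i = np.argwhere(A > D)[0]
        raise ValueError(
            f"{source}: var_reads > total_reads at sample {samples[p]!r}, "
            f"mutation {mutations[i]!r}"
        )


# ---------------------------------------------------------------------------
# cluster aggregation
# ---------------------------------------------------------------------------

def read_cluster_map(path: Union[str, Path]) -> Dict[str, str]:
    """TSV with columns mutation_id, cluster_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("mutation_id", "cluster_id"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return dict(zip(df["mutation_id"], df["cluster_id"]))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def aggregate_clusters(data: ReadCountData, clusters: Mapping[Node, Node]) -> ReadCountData:
    """Collapse mutations into clusters, one column per cluster.

    Per sample and cluster the depth is the median member depth (even-sized
    clusters: mean of the two middle values) rounded half-up, and the
    variant count is that depth times the mean member naive frequency,
    rounded half-up.  Cluster order follows first appearance in the input
    mutation order.
    """
    missing = [mut for mut in data.mutations if mut not in clusters]
    if missing:
        raise ValueError(f"cluster map does not cover mutations {missing!r}")
    order: List[Node] = list(dict.fromkeys(clusters[mut] for mut in data.mutations))
    members: Dict[Node, List[int]] = {c: [] for c in order}
    for j, mut in enumerate(data.mutations):
        members[clusters[mut]].append(j)
    with np.errstate(invalid="ignore", divide="ignore"):
        fhat = np.where(data.D > 0, data.A / np.where(data.D > 0, data.D, 1), 0.0)
    A_out = np.zeros((data.m, len(order)), dtype=np.int64)
    D_out = np.zeros_like(A_out)
    for k, c in enumerate(order):
        idx = members[c]
        med = np.median(data.D[:, idx], axis=1)
        d_new = _round_half_up(med)
        a_new = _round_half_up(d_new * fhat[:, idx].mean(axis=1))
        D_out[:, k] = d_new
        A_out[:, k] = np.minimum(a_new, d_new)  # guard against rounding overshoot
    return ReadCountData(data.samples, order, A_out, D_out)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _tree_obj(tree: Union[MutationTree, BackboneForest], loglik: Optional[float]) -> Dict:
    obj: Dict[str, object] = {"parent": {str(c): str(p) for c, p in tree.parent_map.items()}}
    if isinstance(tree, MutationTree):
        obj["root"] = str(tree.root)
    else:
        obj["roots"] = [str(r) for r in tree.roots]
        obj["nodes"] = sorted(str(v) for v in tree.nodes)
    if loglik is not None:
        obj["loglik"] = loglik
    return obj


def write_result(result: BackboneResult, path: Union[str, Path]) -> None:
    """Serialize an enumeration result as deterministic JSON."""
    obj = {
        "S": [str(s) for s in result.S],
        "rho": result.rho,
        "ell": result.ell_used,
        "trees": [_tree_obj(t, ll) for t, ll in zip(result.trees, result.logliks)],
        "history": result.history,
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_result(path: Union[str, Path]) -> BackboneResult:
    obj = json.loads(Path(path).read_text())
    trees = []
    for tobj in obj["trees"]:
        nodes = set(tobj["parent"]) | set(tobj["parent"].values()) | {tobj["root"]}
        trees.append(make_tree(tobj["parent"], nodes=nodes))
    return BackboneResult(
        S=list(obj["S"]),
        trees=trees,
        logliks=[t["loglik"] for t in obj["trees"]],
        rho=obj["rho"],
        ell_used=obj["ell"],
        history=list(obj["history"]),
    )


def tree_to_dot(tree: Union[MutationTree, BackboneForest], name: str = "T") -> str:
    lines = [f"digraph {name} {{"]
    for v in sorted(tree.nodes, key=repr):
        lines.append(f'  "{v}";')
    for p, c in sorted(tree.edges(), key=lambda e: (repr(e[0]), repr(e[1]))):
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_tree_edges(tree: Union[MutationTree, BackboneForest], path: Union[str, Path]) -> None:
    """Edge-list text: one 'parent<TAB>child' line per edge; roots implicit."""
    lines = [f"{p}\t{c}" for p, c in sorted(tree.edges(), key=lambda e: (repr(e[0]), repr(e[1])))]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_tree_edges(path: Union[str, Path]) -> MutationTree:
    parent: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        p, c = line.split("\t")
        parent[c] = p
    return make_tree(parent)
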