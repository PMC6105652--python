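"""Maximal Clique Centrality (MCC) hub scoring on interaction networks.

MCC(v) = sum over maximal cliques C containing v of (|C|-1)!.  A node whose
neighborhood contains no edges scores its degree (each incident edge is its
own maximal clique, contributing 1! = 1), and a truly isolated node scores
(1-1)! = 1 for its singleton maximal clique.  Factorials are kept in exact
integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from pathlib import Path

import networkx as nx


class NetworkBudgetError(RuntimeError):
    """Graph exceeds the configured node/edge budget for exact enumeration."""


@dataclass(frozen=True)
class HubScore:
    node: str
    mcc: int


def read_network(path, fmt: str | None = None) -> nx.Graph:
    """Read an undirected simple graph from an edge-list TSV or SIF file.

    Edge list: two node columns per line.  SIF: node1 TAB relation TAB
    node2 [TAB node3 ...]; a single-field line declares an isolated node.
    Duplicate edges collapse; self-loops are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "edgelist"
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and not fields[0].strip():
                continue
            if fmt == "sif":
                if len(fields) == 1:
                    graph.add_node(fields[0].strip())
                    continue
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed SIF line")
                source, _relation, *targets = fields
                for target in targets:
                    _add_edge(graph, source, target, path, lineno)
            else:
                if len(fields) == 1:
                    graph.add_node(fields[0].strip())
                    continue
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed edge-list line")
                _add_edge(graph, fields[0], fields[1], path, lineno)
    return graph


def _add_edge(graph: nx.Graph, a: str, b: str, path, lineno: int) -> None:
    a, b = a.strip(), b.strip()
    if not a or not b:
        raise ValueError(f"{path}:{lineno}: empty node name")
    if a == b:
        raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
    graph.add_edge(a, b)


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")


def _check_budget(graph: nx.Graph, max_nodes: int, max_edges: int) -> None:
    if graph.number_of_nodes() > max_nodes or graph.number_of_edges() > max_edges:
        raise NetworkBudgetError(
            f"graph has {graph.number_of_nodes()} nodes / "
            f"{graph.number_of_edges()} edges, exceeding the exact-enumeration "
            f"budget ({max_nodes} nodes / {max_edges} edges)"
        )


def maximal_cliques(graph: nx.Graph, max_nodes: int = 50_000, max_edges: int = 2_000_000) -> list[frozenset]:
    """All maximal cliques (Bron–Kerbosch with pivoting via networkx).

    Isolated nodes appear as singleton cliques.  Refuses graphs beyond the
    node/edge budget rather than truncating silently.
    """
    _check_budget(graph, max_nodes, max_edges)
    return [frozenset(c) for c in nx.find_cliques(graph)]


def mcc_score(graph: nx.Graph, **budget) -> list[HubScore]:
    """Exact MCC for every node, in descending (mcc, name) order."""
    scores = {node: 0 for node in graph.nodes}
    for clique in maximal_cliques(graph, **budget):
        contribution = factorial(len(clique) - 1)
        for node in clique:
            scores[node] += contribution
    return [
        HubScore(node, mcc)
        for node, mcc in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def hub_filter(scores: list[HubScore], min_mcc: int = 10) -> set[str]:
    """Nodes with MCC >= min_mcc (inclusive bound)."""
    return {s.node for s in scores if s.mcc >= min_mcc}


def top_k_subnetwork(graph: nx.Graph, scores: list[HubScore], k: int = 10) -> nx.Graph:
    """Induced subgraph on the k highest-MCC nodes.

    Ties at rank k break lexicographically by node name (the sort order of
    ``mcc_score``), so the result is deterministic.
    """
    if k < 1:
        raise ValueError("need k >= 1")
    ordered = sorted(scores, key=lambda s: (-s.mcc, s.node))
    keep = [s.node for s in ordered[:k]]
    return graph.subgraph(keep).copy()


def scores_to_tsv(scores: list[HubScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tmcc\n")
        for s in scores:
            fh.write(f"{s.node}\t{s.mcc}\n")
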