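"""Markov clustering (MCL) of a confidence-weighted interaction graph.

The input is an undirected edge list with confidence scores in [0, 1];
the medium-confidence filter keeps edges scoring strictly above 0.4 (the
nodes themselves are always kept, so filtered-out genes survive as
singletons).  MCL then alternates expansion (matrix squaring) and
inflation (elementwise power with column renormalization) on the
column-stochastic transition matrix built from the surviving edge
weights, with a self-loop on every node weighted by its maximum incident
edge weight (1.0 for isolated nodes) to stabilize attractors.  Entries
below the pruning threshold are zeroed between iterations.  At
convergence the non-zero structure decomposes the nodes into attractor
systems, which are returned as the cluster partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MIN_SCORE",
    "MCLResult",
    "graph_from_edges",
    "filter_edges",
    "mcl",
    "clusters_to_table",
]

MIN_SCORE = 0.4


def graph_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected weighted graph from a (node_a, node_b, score) table."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b, score = row.node_a, row.node_b, float(row.score)
        if a == b:
            raise ValueError(f"self-loop on node {a!r} in input edge list")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge {a!r}-{b!r}: score {score} outside [0, 1]")
        g.add_edge(a, b, weight=score)
    return g


def filter_edges(graph: nx.Graph, min_score: float = MIN_SCORE) -> nx.Graph:
    """Medium-confidence filter: keep edges scoring strictly above the cut.

    All nodes are preserved; nodes losing every edge become singletons.
    """
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    for a, b, data in graph.edges(data=True):
        score = float(data["weight"])
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge {a!r}-{b!r}: score {score} outside [0, 1]")
        if score > min_score:
            out.add_edge(a, b, weight=score)
    return out


@dataclass
class MCLResult:
    """MCL partition plus convergence diagnostics."""

    clusters: list[list[str]]
    converged: bool
    n_iterations: int
    #: worst |column sum - 1| observed right after any inflation step
    max_column_dev: float

    def membership(self) -> dict[str, int]:
        return {node: i for i, cluster in enumerate(self.clusters)
                for node in cluster}


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    prune_below: float = 1e-5,
    tol: float = 1e-8,
) -> MCLResult:
    """Markov clustering of a weighted undirected graph.

    Returns a partition covering every node exactly once.  On the rare
    non-convergence at ``max_iter`` the current partition is returned
    with ``converged=False``.  Overlapping attractor systems are resolved
    by assigning a node to the cluster of its lexicographically smallest
    attractor.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return MCLResult([], True, 0, 0.0)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data["weight"])
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    # self-loops: max incident weight (1.0 for isolated nodes)
    col_max = m.max(axis=0)
    np.fill_diagonal(m, np.where(col_max > 0, col_max, 1.0))
    m = _normalize_columns(m)

    converged = False
    max_dev = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        expanded = m @ m
        inflated = _normalize_columns(np.power(expanded, inflation))
        inflated[inflated < prune_below] = 0.0
        inflated = _normalize_columns(inflated)
        max_dev = max(max_dev, float(np.abs(inflated.sum(axis=0) - 1.0).max()))
        change = float(np.abs(inflated - m).max())
        m = inflated
        if change < tol:
            converged = True
            break

    clusters = _attractor_systems(m, nodes)
    return MCLResult(clusters=clusters, converged=converged,
                     n_iterations=iterations, max_column_dev=max_dev)


def _attractor_systems(m: np.ndarray, nodes: list[str]) -> list[list[str]]:
    """Read the partition off the (near-)idempotent limit matrix.

    Attractors are nodes with positive diagonal mass; every node joins
    the attractor with the largest flow into it, overlaps resolved toward
    the lexicographically smallest attractor, and attractors flowing into
    each other are unioned into one system.
    """
    n = len(nodes)
    eps = 1e-9
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # numerical corner: treat max-row entries as attractors
        attractors = list({int(np.argmax(m[:, j])) for j in range(n)})
    # union attractor systems: attractors sharing flow belong together
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    attractor_set = set(attractors)
    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] > eps or m[b, a] > eps):
                union(a, b)

    assignment: dict[int, int] = {}
    for j in range(n):
        if j in attractor_set:
            assignment[j] = find(j)
            continue
        targets = [i for i in attractors if m[i, j] > eps]
        if targets:
            # overlap (rare): lexicographically smallest attractor wins
            best = min(targets, key=lambda i: nodes[i])
        else:
            best = int(np.argmax(m[:, j]))
        assignment[j] = find(best)

    groups: dict[int, list[str]] = {}
    for j, root in assignment.items():
        groups.setdefault(root, []).append(nodes[j])
    clusters = [sorted(members) for members in groups.values()]
    return sorted(clusters, key=lambda c: c[0])


def clusters_to_table(result: MCLResult) -> pd.DataFrame:
    """Node -> cluster id table (cluster ids ordered by smallest member)."""
    rows = [(node, i) for i, cluster in enumerate(result.clusters)
            for node in cluster]
    return pd.DataFrame(rows, columns=["node", "cluster"])
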