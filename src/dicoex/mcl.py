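"""Markov clustering (MCL) of a weighted interaction subnetwork.

MCL simulates flow on the graph: the column-stochastic transition matrix is
alternately *expanded* (matrix power — flow spreads) and *inflated*
(entrywise power + renormalisation — strong flow is boosted, weak flow
decays) until it converges to a sparse idempotent matrix whose attractor
rows spell out the clusters.  Inflation controls granularity; the canonical
default of 2.0 is used.

The induced-subgraph entry point mirrors the intended use: cluster the
DEG∩DCE gene set on a user-supplied protein–protein interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class McClusterResult:
    """Ordered clusters with per-cluster node and induced-edge counts.

    ``clusters[i]`` is a sorted gene list; ``labels[i]`` is ``CL{i+1}``.
    Ordering: node count descending, induced edge count descending, then
    smallest member symbol ascending.  ``converged`` is False when the flow
    iteration hit ``max_iter`` (the current interpretation is still
    returned).
    """

    clusters: list[list[str]]
    labels: list[str]
    node_counts: list[int]
    edge_counts: list[int]
    converged: bool

    @property
    def singletons(self) -> list[str]:
        return sorted(c[0] for c in self.clusters if len(c) == 1)


def induced_subgraph(network: nx.Graph, genes) -> nx.Graph:
    """Subgraph of ``network`` induced by ``genes``.

    Genes absent from the network are kept as isolated nodes so the
    clustering partitions the full input gene list.
    """
    genes = list(dict.fromkeys(genes))
    sub = nx.Graph()
    sub.add_nodes_from(genes)
    present = set(genes) & set(network.nodes)
    for a, b, data in network.subgraph(present).edges(data=True):
        sub.add_edge(a, b, weight=data.get("weight", 1.0))
    return sub


def _interpret(m: np.ndarray, nodes: list[str], eps: float) -> list[set[str]]:
    """Read clusters from a (near-)idempotent MCL matrix.

    Attractors are nodes with positive return flow (diagonal entry); each
    attractor's row spans one cluster.  Overlapping attractor clusters are
    merged, which resolves MCL's overlapping-cluster ambiguity
    deterministically.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > eps]
    raw = [set(np.nonzero(m[i] > eps)[0]) | {i} for i in attractors]
    # merge overlapping attractor systems (union-find)
    parent = list(range(len(raw)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(raw)):
        for j in range(i + 1, len(raw)):
            if raw[i] & raw[j]:
                parent[find(j)] = find(i)
    merged: dict[int, set[int]] = {}
    for i, members in enumerate(raw):
        merged.setdefault(find(i), set()).update(members)
    clusters = list(merged.values())
    covered = set().union(*clusters) if clusters else set()
    for i in range(n):  # numerical safety: orphan nodes become singletons
        if i not in covered:
            clusters.append({i})
    return [{nodes[i] for i in c} for c in clusters]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> McClusterResult:
    """Cluster an undirected weighted graph with Markov clustering.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1 for isolated nodes) before column normalisation.  Each
    iteration applies expansion (``matrix_power``), inflation (entrywise
    power, renormalise) and pruning of entries below ``prune``; iteration
    stops when the matrix changes by less than ``tol`` or after
    ``max_iter`` rounds.  Output is invariant under permutation of the input
    node order: nodes are processed in sorted order and clusters are ranked
    canonically.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return McClusterResult([], [], [], [], True)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({a}, {b})")
        if a == b:
            continue
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0  # isolated nodes
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0  # fully pruned column: leave as sink
        m = m / colsum
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break

    clusters = _interpret(m, nodes, eps=prune)
    return rank_clusters(clusters, graph, converged)


def rank_clusters(
    clusters: list[set[str]], graph: nx.Graph, converged: bool = True
) -> McClusterResult:
    """Order clusters by (node count desc, induced edge count desc, smallest
    member asc) and assign labels CL1, CL2, ..."""
    ranked = []
    for members in clusters:
        edges = graph.subgraph(members).number_of_edges()
        ranked.append((sorted(members), len(members), edges))
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0][0]))
    return McClusterResult(
        clusters=[c for c, _, _ in ranked],
        labels=[f"CL{i + 1}" for i in range(len(ranked))],
        node_counts=[nc for _, nc, _ in ranked],
        edge_counts=[ec for _, _, ec in ranked],
        converged=converged,
    )
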