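"""Weighted muscle-network graph metrics (step 6).

Clustering coefficient (segregation), global efficiency (integration) and
betweenness centrality (hubness) on the 8-node weighted muscle graphs built
from the per-component edge weights.  Undirected graphs come from IMCoh-based
components, directed graphs from PDC-based ones.

Conventions: path lengths are the reciprocal edge weights (zero weight = no
edge); the weighted clustering coefficient is the geometric-mean-of-triangle
formulation with weights rescaled by the network maximum; betweenness is
reported both as raw shortest-path counts and normalized by the number of
possible source-target pairs.  Metrics are always computed on the full
weighted graph -- any thresholding is for display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .components import FrequencyComponents

__all__ = [
    "MuscleGraph", "NetworkMetrics",
    "clustering_coefficient", "global_efficiency", "betweenness",
    "metrics_per_component", "graph_from_component",
]


@dataclass
class MuscleGraph:
    """Non-negative weighted graph over the 8 recorded muscles."""

    node_labels: tuple[str, ...]
    adjacency: np.ndarray  # (n, n), zero diagonal
    directed: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, float)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.node_labels):
            raise ValueError("adjacency shape inconsistent with node labels")
        if (a < 0).any():
            raise ValueError("edge weights must be non-negative")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not self.directed and not np.allclose(a, a.T):
            raise ValueError("undirected graph needs a symmetric adjacency")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass
class NetworkMetrics:
    """Per-node and network-mean CC / GE / BC for one frequency component."""

    node_labels: tuple[str, ...]
    cc_per_node: np.ndarray
    cc_mean: float
    ge: float
    bc_per_node: np.ndarray
    bc_mean: float
    component_index: int = 0
    degenerate: bool = False  # all-zero component


def _to_nx(g: MuscleGraph, weight_matrix: np.ndarray):
    cls = nx.DiGraph if g.directed else nx.Graph
    gx = cls()
    gx.add_nodes_from(range(g.n_nodes))
    n = g.n_nodes
    for i in range(n):
        for j in range(n):
            if i == j or (not g.directed and j < i):
                continue
            w = weight_matrix[i, j]
            if w > 0:
                gx.add_edge(i, j, weight=w, length=1.0 / w)
    return gx


def clustering_coefficient(g: MuscleGraph) -> tuple[np.ndarray, float]:
    """Weighted clustering coefficient (geometric-mean triangle form, weights
    max-normalized); directed variant for directed graphs."""
    if g.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    wmax = g.adjacency.max()
    scaled = g.adjacency / wmax if wmax > 0 else g.adjacency
    gx = _to_nx(g, scaled)
    cc = nx.clustering(gx, weight="weight")
    per_node = np.array([cc[i] for i in range(g.n_nodes)])
    return per_node, float(per_node.mean())


def global_efficiency(g: MuscleGraph) -> float:
    """Mean inverse shortest path length over ordered node pairs, distances
    on reciprocal weights; disconnected pairs contribute zero."""
    lengths = np.full_like(g.adjacency, np.inf)
    nz = g.adjacency > 0
    lengths[nz] = 1.0 / g.adjacency[nz]
    d = shortest_path(lengths, method="D", directed=g.directed)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def betweenness(g: MuscleGraph,
                normalized: bool = False) -> tuple[np.ndarray, float]:
    """Node betweenness on reciprocal-weight path lengths.

    ``normalized=False`` returns raw shortest-path fractions summed over
    source-target pairs (each unordered pair counted once in undirected
    graphs); ``normalized=True`` divides by (n-1)(n-2) for directed graphs and
    (n-1)(n-2)/2 for undirected ones.
    """
    gx = _to_nx(g, g.adjacency)
    bc = nx.betweenness_centrality(gx, weight="length", normalized=normalized)
    per_node = np.array([bc[i] for i in range(g.n_nodes)])
    return per_node, float(per_node.mean())


def graph_from_component(fc: FrequencyComponents, component: int,
                         node_labels: tuple[str, ...] | None = None,
                         ) -> MuscleGraph:
    """Map one component's per-pair edge weights back onto the 8x8 adjacency."""
    labels = node_labels or fc.channel_labels
    if not labels:
        raise ValueError("component set carries no channel labels")
    idx = {m: i for i, m in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n))
    for (x, y), w in zip(fc.pair_labels, fc.edge_weights[component]):
        if fc.directed:
            a[idx[x], idx[y]] = w  # row = source, col = target
        else:
            a[idx[x], idx[y]] = a[idx[y], idx[x]] = w
    return MuscleGraph(node_labels=tuple(labels), adjacency=a,
                       directed=fc.directed)


def metrics_per_component(fc: FrequencyComponents,
                          normalized_bc: bool = False) -> list[NetworkMetrics]:
    """All three metrics on the weighted graph of every frequency component."""
    out = []
    for k in range(fc.n_components_K):
        g = graph_from_component(fc, k)
        if not g.adjacency.any():
            n = g.n_nodes
            out.append(NetworkMetrics(
                node_labels=g.node_labels, cc_per_node=np.zeros(n),
                cc_mean=0.0, ge=0.0, bc_per_node=np.zeros(n), bc_mean=0.0,
                component_index=k, degenerate=True))
            continue
        cc, cc_mean = clustering_coefficient(g)
        bc, bc_mean = betweenness(g, normalized=normalized_bc)
        out.append(NetworkMetrics(
            node_labels=g.node_labels, cc_per_node=cc, cc_mean=cc_mean,
            ge=global_efficiency(g), bc_per_node=bc, bc_mean=bc_mean,
            component_index=k))
    return out
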