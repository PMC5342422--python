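"""Biomarker-filtered cancer interaction network, efficiency and pair information centrality.

The network quantifies how much a gene pair's joint removal degrades global
communication.  Efficiency of a graph G with N nodes is

    E(G) = 1/(N(N-1)) * sum_{i != j} 1/d_ij

over ordered node pairs, where d_ij is the shortest-path length when j is
reachable from i, and D(G)+1 otherwise (D(G) = diameter of the reference
network, the largest finite shortest-path length).  The information centrality
of a pair is the relative efficiency drop caused by deleting both nodes:

    C(A, B) = |E(G) - E(G')| / E(G)

with G' = G minus the pair's nodes (deleting an absent node is a no-op).
E(G') is evaluated with the ORIGINAL network's D(G)+1 as the unreachable
penalty, so the penalty base stays fixed under disconnection.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .io import GenePair

logger = logging.getLogger(__name__)

__all__ = [
    "CancerNetwork",
    "build_cancer_network",
    "graph_diameter",
    "network_efficiency",
    "pair_information_centrality",
    "load_edge_list",
]


def load_edge_list(path: str | Path) -> list[GenePair]:
    """Read an interaction edge list: two-column TSV, or SIF (node relation node)."""
    path = Path(path)
    edges: list[GenePair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f for f in line.replace("\t", " ").split(" ") if f]
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: relation type ignored
                a, _, b = fields
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}")
            if a == b:
                continue
            edges.append(GenePair.of(a, b))
    return edges


class CancerNetwork:
    """Simple undirected gene-interaction graph with cached diameter and efficiency."""

    def __init__(self, graph: nx.Graph):
        graph = nx.Graph(graph)
        graph.remove_edges_from(nx.selfloop_edges(graph))
        if graph.number_of_edges() == 0:
            raise ValueError("network has no edges")
        self.graph = graph
        self.diameter: int = graph_diameter(graph)
        self.d_unreachable: int = self.diameter + 1
        self.efficiency: float = network_efficiency(graph, self.d_unreachable)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


def build_cancer_network(
    edges: Iterable[GenePair | tuple[str, str]], biomarkers: Iterable[str]
) -> CancerNetwork:
    """Keep an interaction only if BOTH endpoints are biomarker genes."""
    marker_set = set(biomarkers)
    g = nx.Graph()
    n_in = 0
    for e in edges:
        a, b = tuple(e)
        n_in += 1
        if a == b:
            continue
        if a in marker_set and b in marker_set:
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no interaction survived biomarker filtering ({n_in} input edges, "
            f"{len(marker_set)} biomarkers)"
        )
    net = CancerNetwork(g)
    logger.info(
        "cancer network: %d nodes, %d edges (from %d input edges), diameter %d",
        net.n_nodes, net.n_edges, n_in, net.diameter,
    )
    return net


def _as_graph(net: CancerNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CancerNetwork) else net


def graph_diameter(net: CancerNetwork | nx.Graph) -> int:
    """Largest finite shortest-path length; max over connected components.

    Unreachable pairs are ignored, which keeps D finite on disconnected graphs;
    an edgeless graph has no finite path and is rejected.
    """
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("diameter needs >= 2 nodes")
    best = 0
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            best = max(best, nx.diameter(g.subgraph(comp)))
    if best == 0:
        raise ValueError("graph has no finite path (no edges)")
    return best


def network_efficiency(net: CancerNetwork | nx.Graph, d_unreachable: int) -> float:
    """Average reciprocal shortest-path length with unreachable pairs at 1/d_unreachable.

    Returns 0.0 for graphs with fewer than 2 nodes (degenerate convention).
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    if d_unreachable < 1:
        raise ValueError("d_unreachable must be >= 1")
    total = 0.0
    reachable_ordered = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += 1.0 / d
                reachable_ordered += 1
    unreachable = n * (n - 1) - reachable_ordered
    total += unreachable / d_unreachable
    return total / (n * (n - 1))


def pair_information_centrality(
    net: CancerNetwork,
    pair: GenePair | tuple[str, str],
    recompute_diameter: bool = False,
) -> float:
    """Relative efficiency drop |E(G) - E(G')| / E(G) after deleting the pair's nodes.

    Nodes absent from the network are skipped (no-op removal); a pair entirely
    outside the network scores 0.  With ``recompute_diameter`` the unreachable
    penalty is re-derived from the deleted graph's own diameter instead of the
    reference network's (non-default; the reference penalty keeps the scale
    stable when deletion disconnects the graph).
    """
    if net.efficiency <= 0:
        raise ValueError("reference network has zero efficiency")
    a, b = tuple(pair)
    present = [g for g in (a, b) if g in net.graph]
    if not present:
        return 0.0
    g2 = net.graph.copy()
    g2.remove_nodes_from(present)
    if recompute_diameter and g2.number_of_edges() > 0:
        d_un = graph_diameter(g2) + 1
    else:
        d_un = net.d_unreachable
    e2 = network_efficiency(g2, d_un)
    return abs((net.efficiency - e2) / net.efficiency)
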