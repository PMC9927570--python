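"""Thresholded epistasis networks and their characterisation.

The comprehensive network has variants as nodes and an edge for every pair
whose pairwise information gain strictly exceeds the threshold tau (edge
weight = the gain). Variants with no surviving edge are not carried as
isolated nodes: downstream feature selection operates on connected variants
only. Profiles across a tau grid report node/edge counts, mean degree,
component counts and largest-component size; large components are selected
by a strict size threshold.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from .infotheory import PairScores

__all__ = [
    "EpistasisNetwork",
    "build_network",
    "network_profile",
    "connected_components",
    "select_components",
]


@dataclasses.dataclass
class EpistasisNetwork:
    """Simple undirected graph of variant pairs above an information-gain cut."""

    graph: nx.Graph
    tau: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (min(u, v), max(u, v), d["weight"]) for u, v, d in self.graph.edges(data=True)
        ]

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges())
        return pd.DataFrame(rows, columns=["variant_a", "variant_b", "information_gain"])

    def write_edges(self, path, fmt: str = "tsv") -> None:
        self.edge_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def induced(self, nodes) -> "EpistasisNetwork":
        """Subnetwork induced on ``nodes`` (edges with both endpoints inside)."""
        return EpistasisNetwork(self.graph.subgraph(nodes).copy(), self.tau)


def build_network(scores: PairScores, tau: float) -> EpistasisNetwork:
    """Keep pairs with information gain strictly greater than ``tau``.

    Ties at exactly tau are excluded; nudge tau down to include them.
    """
    g = nx.Graph()
    for a, b, w in scores.iter_pairs():
        if np.isfinite(w) and w > tau:
            g.add_edge(a, b, weight=w)
    return EpistasisNetwork(g, tau)


def connected_components(network: EpistasisNetwork) -> list[set[str]]:
    """Components ordered by size (desc), ties by lexicographically smallest member."""
    comps = [set(c) for c in nx.connected_components(network.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def select_components(
    network: EpistasisNetwork, min_size: int
) -> list[tuple[set[str], EpistasisNetwork]]:
    """Components with strictly more than ``min_size`` nodes, with induced subnetworks."""
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    out = []
    for comp in connected_components(network):
        if len(comp) > min_size:
            out.append((comp, network.induced(comp)))
    return out


def network_profile(scores: PairScores, tau_grid) -> pd.DataFrame:
    """Network statistics across a grid of thresholds.

    Returns one row per tau: n_nodes, n_edges, mean_degree, n_components and
    largest_component_size, each computed on the graph thresholded at that tau.
    """
    tau_grid = list(tau_grid)
    if not tau_grid:
        raise ValueError("tau_grid must be non-empty")
    rows = []
    for tau in tau_grid:
        net = build_network(scores, tau)
        comps = connected_components(net)
        n = net.n_nodes
        rows.append(
            {
                "tau": tau,
                "n_nodes": n,
                "n_edges": net.n_edges,
                "mean_degree": (2 * net.n_edges / n) if n else 0.0,
                "n_components": len(comps),
                "largest_component_size": len(comps[0]) if comps else 0,
            }
        )
    return pd.DataFrame(rows)
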