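"""Whole-network topology statistics: density, efficiency, rank degree.

These are the three Krackhardt-flavoured summary statistics used to
characterise a spatial correlation network as a whole:

* density ``Gd = m / (n (n-1) / 2)`` — realised over possible edges;
* efficiency ``Ge = 1 - V / max(V)`` — one minus the share of redundant
  edges, where an edge is redundant if it exceeds a spanning forest
  (``V = m - (n_active - components)``) and ``max(V)`` is the redundancy of
  the complete graph on each component;
* rank degree ``Gr = 1 - S / max(S)`` — one minus the fraction of node
  pairs that are *symmetrically* reachable. On an undirected graph
  reachability is symmetric, so Gr reduces to the fraction of disconnected
  pairs (0 for any connected graph); the statistic only discriminates
  hierarchy on directed reachability, which is supported by passing a
  directed graph.

Density is computed on the full node universe by default (isolated nodes
count), while efficiency and rank degree operate on the active
(non-isolated) nodes, matching how an excluded station is treated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import json

import networkx as nx
import pandas as pd

from .network_build import SpatialNetwork

__all__ = [
    "TopologySummary",
    "network_density",
    "network_efficiency",
    "network_rank_degree",
    "component_summary",
    "summarize_topology",
]

GraphLike = Union[SpatialNetwork, nx.Graph, nx.DiGraph]
PathLike = Union[str, Path]


@dataclass(frozen=True)
class TopologySummary:
    n_total: int
    n_active: int
    m: int
    components: int
    density: float
    efficiency: float
    rank_degree: float

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: PathLike) -> None:
        pd.DataFrame([asdict(self)]).to_csv(path, index=False)


def _as_graph(network: GraphLike) -> nx.Graph:
    if isinstance(network, SpatialNetwork):
        return network.graph
    return network


def _active_subgraph(g: nx.Graph) -> nx.Graph:
    active = [v for v in g.nodes if g.degree(v) > 0]
    return g.subgraph(active)


def network_density(network: GraphLike, node_basis: str = "all") -> float:
    """Edges over possible edges, ``2m / (n (n-1))``.

    ``node_basis="all"`` (default) counts isolated nodes in n;
    ``"active"`` restricts n to nodes with at least one edge.
    """
    g = _as_graph(network)
    if node_basis == "all":
        n = g.number_of_nodes()
    elif node_basis == "active":
        n = sum(1 for v in g.nodes if g.degree(v) > 0)
    else:
        raise ValueError(f"node_basis must be 'all' or 'active', got {node_basis!r}")
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def network_efficiency(network: GraphLike) -> float:
    """One minus the share of redundant edges, on active nodes.

    ``V = m - (n - c)`` edges beyond a spanning forest (c components);
    ``max(V) = sum over components of (n_c - 1)(n_c - 2) / 2``. Defined as
    1.0 when ``max(V) = 0`` (forests cannot carry redundancy).
    """
    g = _active_subgraph(_as_graph(network))
    if g.number_of_edges() < 1:
        raise ValueError("efficiency needs at least one edge")
    comps = list(nx.connected_components(g))
    n, m, c = g.number_of_nodes(), g.number_of_edges(), len(comps)
    v = m - (n - c)
    v_max = sum((len(comp) - 1) * (len(comp) - 2) // 2 for comp in comps)
    if v_max == 0:
        return 1.0
    return 1.0 - v / v_max


def network_rank_degree(network: GraphLike) -> float:
    """One minus the fraction of symmetrically reachable node pairs.

    Accepts a directed graph for the hierarchy-sensitive variant; on an
    undirected graph this equals the fraction of disconnected pairs.
    """
    g = _as_graph(network)
    if isinstance(g, nx.DiGraph):
        active = [v for v in g.nodes if g.degree(v) > 0]
        g = g.subgraph(active)
        n = g.number_of_nodes()
        if n < 2:
            raise ValueError("rank degree needs >= 2 active nodes")
        s = 0
        reach = {v: set(nx.descendants(g, v)) | {v} for v in g.nodes}
        nodes = list(g.nodes)
        for i, u in enumerate(nodes):
            for w in nodes[i + 1 :]:
                if w in reach[u] and u in reach[w]:
                    s += 1
    else:
        g = _active_subgraph(g)
        n = g.number_of_nodes()
        if n < 2:
            raise ValueError("rank degree needs >= 2 active nodes")
        s = sum(len(c) * (len(c) - 1) // 2 for c in nx.connected_components(g))
    s_max = n * (n - 1) // 2
    return 1.0 - s / s_max


def component_summary(network: GraphLike) -> tuple[int, list[int]]:
    """Connected components over active nodes: (count, sizes descending)."""
    g = _active_subgraph(_as_graph(network))
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return len(sizes), sizes


def summarize_topology(network: GraphLike, node_basis: str = "all") -> TopologySummary:
    g = _as_graph(network)
    n_components, _ = component_summary(network)
    return TopologySummary(
        n_total=g.number_of_nodes(),
        n_active=sum(1 for v in g.nodes if g.degree(v) > 0),
        m=g.number_of_edges(),
        components=n_components,
        density=network_density(network, node_basis=node_basis),
        efficiency=network_efficiency(network),
        rank_degree=network_rank_degree(network),
    )
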