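"""Construction of the air-pollution spatial correlation weighted network.

Nodes are monitoring sites (cities or stations). Two sites are linked when
the Pearson correlation of their daily AQI series reaches a threshold —
by default the mean of all off-diagonal correlation matrix entries, a rule
that keeps the giant component stable across datasets. Each surviving edge
is weighted by the correlation divided by the pair's distance coefficient
(geodesic distance / maximum pairwise distance), and the weights are then
rescaled by their maximum so that they lie in (0, 1].

Sites whose every correlation falls below the threshold end up isolated;
they are kept in the node universe but flagged excluded, mirroring how a
disconnected monitoring station is dropped from path-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import json

import networkx as nx
import numpy as np
import pandas as pd

from .geodesy import pairwise_distance_km
from .panel_io import ReadingsPanel, SitesTable

__all__ = [
    "CorrelationMatrix",
    "DistanceModel",
    "SpatialNetwork",
    "pearson_matrix",
    "mean_offdiag_threshold",
    "distance_coefficients",
    "build_network",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Site × site Pearson coefficients with the mean-off-diagonal threshold."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.entries.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] < 2:
            raise ValueError("correlation matrix must be square, n >= 2")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(m).max() > 1.0 + 1e-9:
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def sites(self) -> list[str]:
        return list(self.entries.columns)

    @property
    def threshold(self) -> float:
        return mean_offdiag_threshold(self)

    def to_csv(self, path: PathLike) -> None:
        self.entries.to_csv(path)


@dataclass(frozen=True)
class DistanceModel:
    """Pairwise geodesic distances (km) and their (0, 1] coefficients."""

    pairwise_km: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.pairwise_km.to_numpy(dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        off = d[~np.eye(d.shape[0], dtype=bool)]
        if off.size and off.min() <= 0.0:
            i, j = np.argwhere((d <= 0) & ~np.eye(d.shape[0], dtype=bool))[0]
            raise ValueError(
                f"sites {self.pairwise_km.index[i]!r} and "
                f"{self.pairwise_km.columns[j]!r} share coordinates "
                "(zero distance would make the edge weight unbounded)"
            )

    @property
    def sites(self) -> list[str]:
        return list(self.pairwise_km.columns)

    @property
    def coefficients(self) -> pd.DataFrame:
        """Distances divided by the maximum distance; farthest pair = 1."""
        d = self.pairwise_km.to_numpy(dtype=float)
        return pd.DataFrame(
            d / d.max(), index=self.pairwise_km.index, columns=self.pairwise_km.columns
        )

    @classmethod
    def from_sites(cls, sites: SitesTable, model: str = "ellipsoid") -> "DistanceModel":
        km = pairwise_distance_km(sites.latitudes, sites.longitudes, model=model)
        ids = sites.site_ids
        return cls(pd.DataFrame(km, index=ids, columns=ids))


@dataclass
class SpatialNetwork:
    """Undirected weighted graph plus construction metadata.

    ``graph`` contains every node of the universe (isolated ones included);
    edges carry ``weight`` in (0, 1] and provenance attributes ``r``
    (correlation), ``distance_km`` and ``pre_weight`` (weight before the
    final rescaling). ``metadata`` records the threshold, the comparison
    rule, the rescaling constant and the excluded (isolated) nodes.
    """

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def all_nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def active_nodes(self) -> list:
        return [v for v in self.graph.nodes if self.graph.degree(v) > 0]

    @property
    def excluded_nodes(self) -> list:
        return [v for v in self.graph.nodes if self.graph.degree(v) == 0]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def active_subgraph(self) -> nx.Graph:
        return self.graph.subgraph(self.active_nodes)

    @classmethod
    def from_graph(cls, graph: nx.Graph, **metadata) -> "SpatialNetwork":
        """Wrap a bare undirected graph; missing edge weights default to 1."""
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        for u, v, data in graph.edges(data=True):
            g.add_edge(u, v, weight=float(data.get("weight", 1.0)))
        return cls(g, dict(metadata))

    # --- writers -----------------------------------------------------------
    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "weight": d.get("weight"),
                "r": d.get("r"),
                "distance_km": d.get("distance_km"),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "r", "distance_km"])

    def write_edgelist(self, path: PathLike) -> None:
        self.edge_table().to_csv(path, index=False)

    def write_graphml(self, path: PathLike) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, **{k: v_ for k, v_ in d.items() if v_ is not None})
        nx.write_graphml(g, path)

    def write_metadata(self, path: PathLike) -> None:
        meta = dict(self.metadata)
        meta["excluded_nodes"] = self.excluded_nodes
        meta["n_nodes"] = len(self.all_nodes)
        meta["n_edges"] = self.n_edges
        Path(path).write_text(json.dumps(meta, indent=2, default=str))


def pearson_matrix(panel: ReadingsPanel) -> CorrelationMatrix:
    """Pearson correlation of every pair of site series over the full panel."""
    values = panel.values
    if values.isna().any().any():
        raise ValueError("panel has missing cells; run impute_missing first")
    if len(values) < 3:
        raise ValueError("need >= 3 dates to estimate correlations")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise ValueError(
            f"site {values.columns[flat[0]]!r} has zero variance; "
            "its correlation is undefined"
        )
    corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(
        pd.DataFrame(corr, index=values.columns, columns=values.columns)
    )


def mean_offdiag_threshold(corr: CorrelationMatrix) -> float:
    """Arithmetic mean of all off-diagonal correlation entries."""
    m = corr.entries.to_numpy(dtype=float)
    mask = ~np.eye(m.shape[0], dtype=bool)
    return float(m[mask].mean())


def distance_coefficients(dist: DistanceModel) -> pd.DataFrame:
    """Linear proportional transformation: d_ij / max(d), in (0, 1]."""
    return dist.coefficients


def build_network(
    corr: CorrelationMatrix,
    dist: DistanceModel,
    comparison: str = "ge",
    threshold: Optional[float] = None,
) -> SpatialNetwork:
    """Assemble the spatial correlation weighted network.

    An edge (i, j) exists when r_ij >= threshold (or > with
    ``comparison="gt"``); its pre-rescaling weight is r_ij divided by the
    pair's distance coefficient, and final weights are pre-rescaling
    weights divided by their maximum over the surviving edges, so the
    strongest edge has weight exactly 1.
    """
    if comparison not in ("ge", "gt"):
        raise ValueError(f"comparison must be 'ge' or 'gt', got {comparison!r}")
    if corr.sites != dist.sites:
        raise ValueError("correlation and distance matrices cover different sites")
    thr = mean_offdiag_threshold(corr) if threshold is None else float(threshold)

    sites = corr.sites
    r = corr.entries.to_numpy(dtype=float)
    km = dist.pairwise_km.to_numpy(dtype=float)
    coef = dist.coefficients.to_numpy(dtype=float)

    edges = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            rij = r[i, j]
            keep = rij >= thr if comparison == "ge" else rij > thr
            if keep:
                if rij <= 0.0:
                    raise ValueError(
                        "threshold admits a non-positive correlation; edge "
                        "weights must be positive — raise the threshold"
                    )
                edges.append((sites[i], sites[j], rij, km[i, j], rij / coef[i, j]))
    if not edges:
        raise ValueError("empty network: no correlation reaches the threshold")

    w_max = max(e[4] for e in edges)
    g = nx.Graph()
    g.add_nodes_from(sites)
    for u, v, rij, d_km, pre in edges:
        g.add_edge(u, v, weight=pre / w_max, r=rij, distance_km=d_km, pre_weight=pre)

    return SpatialNetwork(
        g,
        metadata={
            "threshold": thr,
            "comparison": comparison,
            "weight_normalizer": w_max,
        },
    )
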