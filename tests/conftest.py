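import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aqinet import ReadingsPanel, SitesTable, SpatialNetwork

# Beijing monitoring stations (id, name, lat, lon, category)
BEIJING_STATIONS = [
    ("1001A", "Wanshouxigong", 39.867, 116.366, "Urban"),
    ("1002A", "Dingling", 40.286, 116.170, "Suburban"),
    ("1003A", "Dongsi", 39.952, 116.434, "Urban"),
    ("1004A", "Tiantan", 39.874, 116.434, "Urban"),
    ("1005A", "Nongzhanguan", 39.972, 116.473, "Urban"),
    ("1006A", "Guanyuan", 39.942, 116.361, "Urban"),
    ("1007A", "Haidianquwanliu", 39.993, 116.315, "Urban"),
    ("1008A", "Shunyixincheng", 40.144, 116.720, "Suburban"),
    ("1009A", "Huairouzhen", 40.394, 116.644, "Suburban"),
    ("1010A", "Changpingzhen", 40.195, 116.230, "Suburban"),
    ("1011A", "Aotizhongxin", 40.003, 116.407, "Urban"),
    ("1012A", "Gucheng", 39.928, 116.22, "Urban"),
]


@pytest.fixture
def beijing_sites() -> SitesTable:
    return SitesTable(
        pd.DataFrame(
            BEIJING_STATIONS,
            columns=["site_id", "name", "latitude", "longitude", "category"],
        )
    )


@pytest.fixture
def beijing_sites_csv(tmp_path, beijing_sites):
    path = tmp_path / "sites.csv"
    beijing_sites.to_csv(path)
    return path


@pytest.fixture
def daily_panel() -> ReadingsPanel:
    """Small complete 3-site daily panel."""
    idx = pd.date_range("2021-01-01", periods=6, freq="D")
    return ReadingsPanel(
        pd.DataFrame(
            {"A": [50.0, 60, 55, 70, 65, 80], "B": [40.0, 52, 47, 66, 58, 75],
             "C": [90.0, 70, 85, 60, 72, 55]},
            index=idx,
        )
    )


def random_weighted_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Erdos-Renyi graph with Uniform(0.05, 1] weights."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j, weight=float(rng.uniform(0.05, 1.0)))
    return g


def connected_gnm(n: int, m: int, seed: int = 0) -> nx.Graph:
    """Random connected simple graph with exactly n nodes and m edges."""
    assert m >= n - 1
    for s in range(seed, seed + 1000):
        g = nx.gnm_random_graph(n, m, seed=s)
        if nx.is_connected(g):
            return g
    raise AssertionError("could not draw a connected graph")


def wrap(graph: nx.Graph) -> SpatialNetwork:
    return SpatialNetwork.from_graph(graph)
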