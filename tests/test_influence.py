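import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aqinet import (
    InfluenceConfig,
    global_influence,
    local_influence,
    shortest_distance_matrix,
    weighted_degree,
    wlgi_scores,
)
from conftest import random_weighted_graph, wrap

# Published per-node values for the three agglomeration networks
# (dw, n, W_GI, W_LGI); used as wiring checks of the score formulas.
PEARL_RIVER_DELTA = {
    "Guangzhou": (2.036, 9, 8.743, 1.978),
    "Foshan": (2.384, 9, 8.774, 2.324),
    "Zhongshan": (2.026, 9, 8.825, 1.986),
    "Jiangmen": (2.132, 9, 9.038, 2.141),
    "Zhaoqing": (0.488, 9, 8.395, 0.456),
}
YANGTZE_RIVER_DELTA = {
    "Zhenjiang": (3.771, 26, 38.164, 5.535),
    "Nanjing": (3.465, 26, 38.834, 5.176),
    "Shanghai": (1.767, 26, 38.689, 2.629),
    "Jinhua": (0.473, 26, 36.987, 0.673),
}


def brute_force_shortest(g: nx.Graph, lengths: dict) -> dict:
    """All-pairs shortest distance by exhaustive simple-path enumeration."""
    nodes = list(g.nodes)
    out = {}
    for a, b in itertools.combinations(nodes, 2):
        best = math.inf
        for path in _simple_paths(g, a, b):
            total = sum(lengths[frozenset(e)] for e in zip(path, path[1:]))
            best = min(best, total)
        out[frozenset((a, b))] = best
    return out


def _simple_paths(g, a, b, seen=None, path=None):
    seen = seen or {a}
    path = path or [a]
    if a == b:
        yield path
        return
    for nxt in g.neighbors(a):
        if nxt not in seen:
            yield from _simple_paths(g, nxt, b, seen | {nxt}, path + [nxt])


class TestWeightedDegree:
    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", weight=0.7)
        assert weighted_degree(wrap(g), "c") == 0.0

    def test_star_center(self):
        g = nx.star_graph(3)
        nx.set_edge_attributes(g, 0.5, "weight")
        assert weighted_degree(wrap(g), 0) == pytest.approx(1.5)

    def test_matches_adjacency_row_sums(self):
        rng = np.random.default_rng(23)
        g = random_weighted_graph(6, 0.6, rng)
        adj = nx.to_numpy_array(g, weight="weight")
        for i, v in enumerate(g.nodes):
            assert weighted_degree(wrap(g), v) == pytest.approx(adj[i].sum())

    def test_unknown_node(self):
        g = nx.Graph([(0, 1)])
        with pytest.raises(KeyError):
            weighted_degree(wrap(g), 99)


class TestLocalInfluence:
    @pytest.mark.parametrize(
        "dw, n, expected",
        [(2.601, 13, 0.200), (2.384, 9, 0.265), (0.0, 5, 0.0)],
    )
    def test_published_rows_and_zero(self, dw, n, expected):
        assert local_influence(dw, n) == pytest.approx(expected, abs=5e-4)


class TestShortestDistances:
    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.4)
        d = shortest_distance_matrix(wrap(g))
        assert d.loc["a", "b"] == pytest.approx(0.4)

    def test_two_hop_lighter_than_direct(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.6)
        g.add_edge("a", "c", weight=0.2)
        g.add_edge("c", "b", weight=0.3)
        d = shortest_distance_matrix(wrap(g))
        assert d.loc["a", "b"] == pytest.approx(0.5)

    def test_disconnected_pairs_infinite(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.4)
        g.add_edge("c", "d", weight=0.2)
        d = shortest_distance_matrix(wrap(g))
        assert math.isinf(d.loc["a", "c"])

    def test_inverse_mode_uses_reciprocal_lengths(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        d = shortest_distance_matrix(wrap(g), mode="inverse_weight_sum")
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            g = random_weighted_graph(7, 0.45, rng)
            active = [v for v in g.nodes if g.degree(v) > 0]
            if len(active) < 2:
                continue
            h = g.subgraph(active)
            lengths = {
                frozenset((u, v)): d["weight"] for u, v, d in h.edges(data=True)
            }
            expected = brute_force_shortest(h, lengths)
            got = shortest_distance_matrix(wrap(g))
            for pair, dist in expected.items():
                a, b = tuple(pair)
                assert got.loc[a, b] == pytest.approx(dist)


class TestGlobalInfluence:
    def test_two_node_network_theta_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.37)
        for v in ("a", "b"):
            assert global_influence(wrap(g), v) == pytest.approx(1.0)

    def test_path_graph_hand_evaluated(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=0.5)
        # W_GI(A) = dw(B)/1.0 + dw(C)/1.5 = 1.5 + 0.333...
        assert global_influence(wrap(g), "A") == pytest.approx(1.5 + 0.5 / 1.5)

    def test_contributions_only_from_own_component(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.4)
        g.add_edge("c", "d", weight=0.9)
        assert global_influence(wrap(g), "a") == pytest.approx(0.4 / 0.4)

    def test_theta_damps_score(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        lo = global_influence(wrap(g), "a", InfluenceConfig(theta=1.0))
        hi = global_influence(wrap(g), "a", InfluenceConfig(theta=0.0))
        assert lo < hi


class TestWlgiScores:
    def test_published_product_wiring(self):
        """Printed dw/n times printed W_GI reproduces printed W_LGI."""
        for table in (PEARL_RIVER_DELTA, YANGTZE_RIVER_DELTA):
            for city, (dw, n, w_gi, w_lgi) in table.items():
                w_li = local_influence(dw, n)
                assert w_li * w_gi == pytest.approx(w_lgi, abs=2e-3), city

    def test_isolated_node_scores_zero_ranks_last(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        g.add_edge(0, 1, weight=0.5)
        g.add_edge(1, 2, weight=0.8)
        g.add_edge(0, 2, weight=0.3)
        g.add_edge(2, 3, weight=1.0)
        table = wlgi_scores(wrap(g)).set_index("node")
        assert table.loc[4, "W_LGI"] == 0.0
        assert table.loc[4, "rank"] == 5
        assert sorted(table["rank"]) == [1, 2, 3, 4, 5]

    def test_weighted_star_center_wins(self):
        g = nx.Graph()
        for leaf in "bcde":
            g.add_edge("a", leaf, weight=0.6)
        table = wlgi_scores(wrap(g))
        assert table["node"].iloc[0] == "a"
        assert table["W_LGI"].iloc[0] > table["W_LGI"].iloc[1]

    def test_complete_equal_weight_graph_symmetric(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 0.5, "weight")
        table = wlgi_scores(wrap(g))
        assert table["W_LGI"].nunique() == 1

    def test_product_identity_and_dw_sum(self):
        rng = np.random.default_rng(31)
        g = random_weighted_graph(9, 0.5, rng)
        table = wlgi_scores(wrap(g))
        np.testing.assert_allclose(
            table["W_LGI"], table["W_LI"] * table["W_GI"], rtol=1e-12
        )
        total_w = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert table["dw"].sum() == pytest.approx(2 * total_w)

    def test_theta_sweep_leaves_local_columns_fixed(self):
        rng = np.random.default_rng(37)
        g = random_weighted_graph(8, 0.5, rng)
        tables = {
            th: wlgi_scores(wrap(g), InfluenceConfig(theta=th))
            .set_index("node")
            .sort_index()
            for th in (0.0, 0.5, 1.0)
        }
        base = tables[0.0]
        for th in (0.5, 1.0):
            pd.testing.assert_series_equal(base["dw"], tables[th]["dw"])
            pd.testing.assert_series_equal(base["W_LI"], tables[th]["W_LI"])
            assert not np.allclose(base["W_GI"], tables[th]["W_GI"])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.floats(0.1, 50.0))
def test_weight_rescaling_preserves_ranking_with_theta_zero(seed, scale):
    """With theta=0 and weight-sum paths, W_LGI scales by c and ranks hold."""
    rng = np.random.default_rng(seed)
    g = random_weighted_graph(8, 0.5, rng)
    active = [v for v in g.nodes if g.degree(v) > 0]
    if len(active) < 3:
        return
    base = wlgi_scores(wrap(g)).set_index("node")
    scaled_graph = g.copy()
    for u, v in scaled_graph.edges:
        scaled_graph.edges[u, v]["weight"] *= scale
    scaled = wlgi_scores(wrap(scaled_graph)).set_index("node")
    pd.testing.assert_series_equal(base["rank"], scaled["rank"])
    np.testing.assert_allclose(
        scaled["W_LGI"], base["W_LGI"] * scale, rtol=1e-9
    )


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_score_relabeling_invariance(seed):
    rng = np.random.default_rng(seed)
    g = random_weighted_graph(7, 0.5, rng)
    mapping = {v: f"x{v}" for v in g.nodes}
    base = wlgi_scores(wrap(g)).set_index("node")
    relabeled = wlgi_scores(wrap(nx.relabel_nodes(g, mapping))).set_index("node")
    for v in g.nodes:
        assert relabeled.loc[mapping[v], "W_LGI"] == pytest.approx(
            base.loc[v, "W_LGI"]
        )
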