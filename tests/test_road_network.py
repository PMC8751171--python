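"""Segment centrality and space-syntax metrics against brute-force
all-pairs enumeration."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString

from mslur.geo_io import RoadGraph
from mslur.road_network import (build_dual_graph, centrality_metrics,
                                diamond_value, segment_metrics,
                                syntax_metrics)

from .oracles import (brute_betweenness, brute_closeness, brute_mean_depth,
                      floyd_warshall)


def path_graph(n_segments: int, length: float = 100.0) -> RoadGraph:
    rg = RoadGraph()
    for i in range(n_segments):
        rg.add_edge(LineString([(i * length, 0), ((i + 1) * length, 0)]),
                    "ordinary")
    return rg


def star_graph(k: int) -> RoadGraph:
    rg = RoadGraph()
    for i in range(k):
        a = 2 * math.pi * i / k
        rg.add_edge(LineString([(0, 0), (100 * math.cos(a),
                                         100 * math.sin(a))]), "ordinary")
    return rg


def random_road_graph(seed: int, n_nodes: int = 10) -> RoadGraph:
    """Random connected planar-ish network with <= 30 primal nodes."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1000, size=(n_nodes, 2))
    rg = RoadGraph()
    # spanning path + random chords
    order = rng.permutation(n_nodes)
    for a, b in zip(order, order[1:]):
        rg.add_edge(LineString([tuple(pts[a]), tuple(pts[b])]), "ordinary")
    for _ in range(n_nodes // 2):
        a, b = rng.integers(0, n_nodes, 2)
        if a != b and not rg.graph.has_edge(a, b):
            try:
                rg.add_edge(LineString([tuple(pts[a]), tuple(pts[b])]),
                            "ordinary")
            except ValueError:
                pass
    return rg


def _dense_matrices(roads: RoadGraph):
    """Dense distance matrix of the midpoint-augmented primal graph, plus
    the midpoint node order (by edge id)."""
    g = nx.Graph()
    for nid in roads.graph.nodes:
        g.add_node(("n", nid), **roads.graph.nodes[nid])
    for rec in roads.segments():
        mid = rec["geometry"].interpolate(0.5, normalized=True)
        m = ("m", rec["edge_id"])
        g.add_node(m, x=mid.x, y=mid.y)
        g.add_edge(("n", rec["u"]), m, length=rec["length"] / 2)
        g.add_edge(m, ("n", rec["v"]), length=rec["length"] / 2)
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, d in g.edges(data=True):
        dist[idx[u], idx[v]] = min(dist[idx[u], idx[v]], d["length"])
        dist[idx[v], idx[u]] = dist[idx[u], idx[v]]
    return g, nodes, idx, dist


class TestDualGraph:
    def test_path_of_three(self):
        dual = build_dual_graph(path_graph(3))
        assert sorted(dual.edges) == [(0, 1), (1, 2)]

    def test_star_becomes_complete(self):
        dual = build_dual_graph(star_graph(4))
        assert dual.number_of_edges() == 6  # K4

    def test_components_preserved(self):
        rg = RoadGraph()
        rg.add_edge(LineString([(0, 0), (100, 0)]), "ordinary")
        rg.add_edge(LineString([(0, 500), (100, 500)]), "ordinary")
        dual = build_dual_graph(rg)
        assert nx.number_connected_components(dual) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_dual_graph(RoadGraph())


class TestCentrality:
    def test_three_collinear_betweenness(self):
        df = centrality_metrics(path_graph(3))
        assert df.loc[1, "BETWEEN"] == pytest.approx(
            df["BETWEEN"].max())
        # middle midpoint carries all end-to-end shortest paths
        assert df.loc[1, "BETWEEN"] > df.loc[0, "BETWEEN"]
        assert df.loc[0, "BETWEEN"] == pytest.approx(df.loc[2, "BETWEEN"])

    def test_straightness_one_on_a_line(self):
        df = centrality_metrics(path_graph(4))
        assert np.allclose(df["STRAIGHT"], 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        roads = random_road_graph(seed, n_nodes=8)
        df = centrality_metrics(roads)
        _, nodes, idx, dist = _dense_matrices(roads)
        btw = brute_betweenness(dist)
        close = brute_closeness(dist)
        for rec in roads.segments():
            i = idx[("m", rec["edge_id"])]
            assert df.loc[rec["edge_id"], "BETWEEN"] == pytest.approx(
                btw[i], abs=1e-9)
            assert df.loc[rec["edge_id"], "CLOSE"] == pytest.approx(
                close[i], rel=1e-9)

    def test_straightness_matches_direct_enumeration(self):
        roads = random_road_graph(3, n_nodes=7)
        df = centrality_metrics(roads)
        g, nodes, idx, dist = _dense_matrices(roads)
        d, _ = floyd_warshall(dist)
        mids = [v for v in nodes if v[0] == "m"]
        for v in mids:
            ratios = []
            for u in mids:
                if u == v or not np.isfinite(d[idx[v], idx[u]]):
                    continue
                eu = math.hypot(g.nodes[u]["x"] - g.nodes[v]["x"],
                                g.nodes[u]["y"] - g.nodes[v]["y"])
                ratios.append(eu / d[idx[v], idx[u]])
            assert df.loc[v[1], "STRAIGHT"] == pytest.approx(
                np.mean(ratios), rel=1e-9)


class TestSyntax:
    def test_star_control_values(self):
        k = 5
        dual = build_dual_graph(star_graph(k))  # K5: every degree = 4
        df = syntax_metrics(dual)
        assert np.allclose(df["CONTROL"], 1.0)  # regular graph
        # a genuine hub: dual of a path + one crossing
        dual2 = nx.star_graph(k)  # hub 0, leaves 1..k
        df2 = syntax_metrics(dual2)
        assert df2.loc[0, "CONTROL"] == pytest.approx(k)
        assert df2.loc[1, "CONTROL"] == pytest.approx(1.0 / k)

    def test_path_mean_depth(self):
        dual = build_dual_graph(path_graph(3))
        df = syntax_metrics(dual)
        assert df.loc[0, "MDEPTH"] == pytest.approx(1.5)
        assert df.loc[1, "MDEPTH"] == pytest.approx(1.0)

    def test_mean_depth_matches_brute_force(self):
        dual = build_dual_graph(random_road_graph(5, n_nodes=9))
        df = syntax_metrics(dual)
        nodes = sorted(dual.nodes)
        adj = nx.to_numpy_array(dual, nodelist=nodes)
        md = brute_mean_depth(adj)
        for i, v in enumerate(nodes):
            assert df.loc[v, "MDEPTH"] == pytest.approx(md[i], abs=1e-9)

    def test_integration_follows_diamond_normalization(self):
        dual = build_dual_graph(random_road_graph(2, n_nodes=8))
        df = syntax_metrics(dual)
        k = dual.number_of_nodes()
        for v in dual.nodes:
            md = df.loc[v, "MDEPTH"]
            ra = 2 * (md - 1) / (k - 2)
            assert df.loc[v, "GINTEG"] == pytest.approx(
                diamond_value(k) / ra, rel=1e-9)

    def test_small_component_integration_nan(self):
        rg = path_graph(2)
        with pytest.warns(UserWarning, match="k <= 2"):
            df = syntax_metrics(build_dual_graph(rg))
        assert df["GINTEG"].isna().all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_control_sums_to_node_count(self, seed):
        dual = build_dual_graph(random_road_graph(seed, n_nodes=9))
        df = syntax_metrics(dual)
        assert df["CONTROL"].sum() == pytest.approx(
            dual.number_of_nodes(), abs=1e-9)


def test_relabeling_invariance():
    roads = random_road_graph(11, n_nodes=8)
    df1 = segment_metrics(roads)
    # rebuild with shuffled edge insertion order -> new ids, same geometry
    segs = roads.segments()
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(segs))
    rg2 = RoadGraph()
    new_id_of = {}
    for new_id, j in enumerate(perm):
        rg2.add_edge(segs[j]["geometry"], segs[j]["road_class"],
                     edge_id=new_id)
        new_id_of[segs[j]["edge_id"]] = new_id
    df2 = segment_metrics(rg2)
    for old, new in new_id_of.items():
        np.testing.assert_allclose(df1.loc[old].to_numpy(dtype=float),
                                   df2.loc[new].to_numpy(dtype=float),
                                   rtol=1e-9, equal_nan=True)
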