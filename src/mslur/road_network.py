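"""Road-segment centrality and space-syntax metrics used as traffic proxies.

Two graph views are used:

* the **primal** graph (junction nodes, segment edges weighted by metric
  length) with each segment's midpoint inserted as an evaluation node —
  yields normalized straightness, betweenness and closeness per segment;
* the **dual** (segment adjacency) graph — one node per road segment,
  adjacent iff the segments share an endpoint — yields the space-syntax
  metrics: connectivity, control value, mean depth, global and local
  integration.

Integration follows the standard space-syntax normalization: relative
asymmetry ``RA = 2 (MD - 1)/(k - 2)`` is divided by the diamond value
``D_k`` to give RRA, and integration is ``1/RRA``.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .geo_io import RoadGraph

__all__ = [
    "build_dual_graph",
    "centrality_metrics",
    "syntax_metrics",
    "segment_metrics",
    "diamond_value",
]

CENTRALITY_COLS = ["STRAIGHT", "BETWEEN", "CLOSE"]
SYNTAX_COLS = ["CONNECT", "CONTROL", "MDEPTH", "GINTEG", "LINTEG"]


def build_dual_graph(roads: RoadGraph) -> nx.Graph:
    """Segment-adjacency (dual) graph: one node per segment, edges between
    segments sharing an endpoint."""
    if roads.n_edges == 0:
        raise ValueError("empty road graph")
    dual = nx.Graph()
    incident: dict[int, list[int]] = {}
    for rec in roads.segments():
        dual.add_node(rec["edge_id"])
        for endpoint in (rec["u"], rec["v"]):
            incident.setdefault(endpoint, []).append(rec["edge_id"])
    for edge_ids in incident.values():
        for i, a in enumerate(edge_ids):
            for b in edge_ids[i + 1:]:
                if a != b:
                    dual.add_edge(a, b)
    return dual


def _midpoint_graph(roads: RoadGraph):
    """Primal graph with each segment's midpoint inserted as a node.

    Returns (graph, {edge_id: midpoint_node}); edge weights are metric
    lengths along the segment polylines.
    """
    g = nx.Graph()
    for nid in roads.graph.nodes:
        x, y = roads.node_xy(nid)
        g.add_node(("n", nid), x=x, y=y)
    midpoints = {}
    for rec in roads.segments():
        mid = rec["geometry"].interpolate(0.5, normalized=True)
        mnode = ("m", rec["edge_id"])
        g.add_node(mnode, x=mid.x, y=mid.y)
        half = rec["length"] / 2.0
        g.add_edge(("n", rec["u"]), mnode, length=half)
        g.add_edge(mnode, ("n", rec["v"]), length=half)
        midpoints[rec["edge_id"]] = mnode
    return g, midpoints


def centrality_metrics(roads: RoadGraph) -> pd.DataFrame:
    """Length-weighted straightness, betweenness and closeness per segment.

    Metrics are evaluated at segment midpoints on the midpoint-augmented
    primal graph, within each connected component:

    * BETWEEN — shortest-path betweenness, normalized by (N-1)(N-2)/2 pairs
      (N = component node count); 0 for components smaller than 3 nodes.
    * CLOSE — (N-1) / sum of network distances to all other nodes (1/m).
    * STRAIGHT — mean over other midpoints of Euclidean/network distance.
    """
    if roads.n_edges == 0:
        raise ValueError("empty road graph")
    g, midpoints = _midpoint_graph(roads)
    rows = {}
    for comp_nodes in nx.connected_components(g):
        sub = g.subgraph(comp_nodes)
        n = sub.number_of_nodes()
        btw = (nx.betweenness_centrality(sub, normalized=True, weight="length")
               if n >= 3 else {v: 0.0 for v in sub})
        close = nx.closeness_centrality(sub, distance="length",
                                        wf_improved=False)
        comp_mids = [v for v in sub if v[0] == "m"]
        for v in comp_mids:
            dists = nx.single_source_dijkstra_path_length(sub, v,
                                                          weight="length")
            x0, y0 = sub.nodes[v]["x"], sub.nodes[v]["y"]
            ratios = []
            for u in comp_mids:
                if u == v:
                    continue
                d_net = dists[u]
                d_euc = math.hypot(sub.nodes[u]["x"] - x0,
                                   sub.nodes[u]["y"] - y0)
                if d_net > 0:
                    ratios.append(d_euc / d_net)
            straight = float(np.mean(ratios)) if ratios else 1.0
            rows[v[1]] = {"STRAIGHT": straight, "BETWEEN": btw[v],
                          "CLOSE": close[v]}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "segment_id"
    return df[CENTRALITY_COLS]


def diamond_value(k: int) -> float:
    """Diamond-graph normalization D_k for integration (k >= 3)."""
    if k < 3:
        raise ValueError("diamond value undefined for k < 3")
    return 2.0 * (k * (math.log2((k + 2.0) / 3.0) - 1.0) + 1.0) / (
        (k - 1.0) * (k - 2.0))


def _integration(md: float, k: int) -> float:
    """1/RRA from mean depth and element count; nan when degenerate."""
    if k <= 2:
        return math.nan
    ra = 2.0 * (md - 1.0) / (k - 2.0)
    rra = ra / diamond_value(k)
    if rra <= 0:
        return math.nan
    return 1.0 / rra


def syntax_metrics(dual: nx.Graph, local_radius: int = 3) -> pd.DataFrame:
    """Space-syntax metrics on the segment dual graph.

    CONNECT = degree; CONTROL = sum of 1/degree over neighbors;
    MDEPTH = mean topological distance to every other element in the
    component; GINTEG/LINTEG = 1/RRA globally / within ``local_radius``
    topological steps.  Components with k <= 2 yield NaN integration.
    """
    if dual.number_of_nodes() == 0:
        raise ValueError("empty dual graph")
    rows = {}
    warned = False
    for comp_nodes in nx.connected_components(dual):
        sub = dual.subgraph(comp_nodes)
        k = sub.number_of_nodes()
        for v in sub:
            depths = nx.single_source_shortest_path_length(sub, v)
            deg = sub.degree(v)
            control = sum(1.0 / sub.degree(u) for u in sub.neighbors(v))
            if k >= 2:
                md = sum(depths.values()) / (k - 1)
            else:
                md = math.nan
            ginteg = _integration(md, k)
            local_nodes = [u for u, d in depths.items()
                           if d <= local_radius]
            kl = len(local_nodes)
            if kl >= 2:
                loc = sub.subgraph(local_nodes)
                ldepths = nx.single_source_shortest_path_length(loc, v)
                mdl = sum(ldepths.values()) / (kl - 1)
                linteg = _integration(mdl, kl)
            else:
                linteg = math.nan
            if (math.isnan(ginteg) or math.isnan(linteg)) and not warned:
                warnings.warn("integration undefined (component with k <= 2 "
                              "elements, or zero relative asymmetry); "
                              "emitting NaN")
                warned = True
            rows[v] = {"CONNECT": deg, "CONTROL": control, "MDEPTH": md,
                       "GINTEG": ginteg, "LINTEG": linteg}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "segment_id"
    return df[SYNTAX_COLS]


def segment_metrics(roads: RoadGraph, local_radius: int = 3) -> pd.DataFrame:
    """All eight per-segment metrics (centrality + syntax), one row per
    segment id."""
    cent = centrality_metrics(roads)
    syn = syntax_metrics(build_dual_graph(roads), local_radius=local_radius)
    return cent.join(syn)
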