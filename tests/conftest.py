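"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive algorithms (recursive definitions, path
enumeration on a cell-adjacency graph) so they share no code with the
implementations they check.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from riverscale.focal import snap_barrier
from riverscale.network import Barrier, Edge, RiverNetwork, discretize


def random_tree(rng: np.random.Generator, n_edges: int, max_length: float = 600.0,
                barrier_prob: float = 0.0) -> RiverNetwork:
    """Random rooted tree: each new edge attaches above a uniformly chosen node."""
    edges = [Edge("e0", "n1", "outlet", float(rng.uniform(60, max_length)))]
    nodes = ["n1"]
    for k in range(1, n_edges):
        down = nodes[int(rng.integers(len(nodes)))]
        up = f"n{k + 1}"
        edges.append(Edge(f"e{k}", up, down, float(rng.uniform(60, max_length))))
        nodes.append(up)
    barriers = []
    for e in edges:
        if rng.random() < barrier_prob:
            barriers.append(Barrier(e.edge_id, float(rng.uniform(0, e.length_m)),
                                    passable=bool(rng.random() < 0.3)))
    return RiverNetwork(edges, barriers)


# -- recursive stream-order oracles -----------------------------------------

def brute_headwater_count(net: RiverNetwork, edge_id) -> int:
    """Number of headwater edges upstream of (and including) an edge."""
    e = net.edges[edge_id]
    tribs = net.tributaries(e.up_node)
    if not tribs:
        return 1
    return sum(brute_headwater_count(net, t.edge_id) for t in tribs)


def brute_strahler(net: RiverNetwork, edge_id) -> int:
    e = net.edges[edge_id]
    tribs = net.tributaries(e.up_node)
    if not tribs:
        return 1
    vals = sorted(brute_strahler(net, t.edge_id) for t in tribs)
    if len(vals) >= 2 and vals[-1] == vals[-2]:
        return vals[-1] + 1
    return vals[-1]


def brute_distance_to_outlet(net: RiverNetwork, edge_id, chainage: float) -> float:
    """Walk the unique downstream path, accumulating lengths."""
    e = net.edges[edge_id]
    total = e.length_m - chainage
    node = e.down_node
    while node != net.outlet_node:
        e = net.downstream_edge(node)
        total += e.length_m
        node = e.down_node
    return total


# -- cell-graph neighbourhood oracle ----------------------------------------

def cell_graph(net: RiverNetwork, cell_length: float) -> tuple[nx.Graph, dict]:
    """Adjacency graph of discretised cells with barrier crossings removed.

    Nodes are (edge_id, index); adjacent cells are joined with the distance
    between their centres, including cliques over all cells meeting at a
    confluence node.  Impassable barriers (snapped to cell boundaries)
    delete the crossing adjacency.
    """
    cells = discretize(net, cell_length)
    by_edge: dict = {}
    for c in cells:
        by_edge.setdefault(c.edge_id, []).append(c)

    blocked_interior = set()  # (edge_id, boundary chainage)
    blocked_start, blocked_end = set(), set()
    for b in net.barriers:
        if b.passable:
            continue
        e = net.edges[b.edge_id]
        s = snap_barrier(b.chainage_m, e.length_m, cell_length)
        if s == 0.0:
            blocked_start.add(b.edge_id)
        elif s == e.length_m:
            blocked_end.add(b.edge_id)
        else:
            blocked_interior.add((b.edge_id, round(s, 6)))

    g = nx.Graph()
    for c in cells:
        g.add_node((c.edge_id, c.index))
    for eid, cs in by_edge.items():
        for a, b in zip(cs, cs[1:]):
            if (eid, round(a.end_m, 6)) in blocked_interior:
                continue
            g.add_edge((eid, a.index), (eid, b.index), weight=b.center_m - a.center_m)
    # cliques at nodes: last cell of each arriving edge, first cell of the leaving edge
    incident: dict = {}
    for eid, cs in by_edge.items():
        e = net.edges[eid]
        if eid not in blocked_start:
            incident.setdefault(e.up_node, []).append(
                ((eid, cs[0].index), cs[0].center_m)
            )
        if eid not in blocked_end:
            incident.setdefault(e.down_node, []).append(
                ((eid, cs[-1].index), e.length_m - cs[-1].center_m)
            )
    for node, items in incident.items():
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (ka, da), (kb, db) = items[i], items[j]
                w = da + db
                if g.has_edge(ka, kb):
                    w = min(w, g.edges[ka, kb]["weight"])
                g.add_edge(ka, kb, weight=w)
    return g, by_edge


def brute_neighborhood(net: RiverNetwork, site, d: float, cell_length: float) -> set:
    """Cells reachable within distance d on the cell-adjacency graph."""
    g, by_edge = cell_graph(net, cell_length)
    cs = by_edge[site.edge_id]
    idx = min(int(site.chainage_m // cell_length), len(cs) - 1)
    start = (site.edge_id, idx)
    dist = nx.single_source_dijkstra_path_length(g, start)
    return {k for k, v in dist.items() if v <= d + 1e-6}


@pytest.fixture
def rng():
    return np.random.default_rng(20150)
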