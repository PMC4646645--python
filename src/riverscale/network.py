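"""River network as a directed tree draining to a single outlet.

The network is a vector graph: edges are reaches with a length in metres,
oriented from their upstream node to their downstream node.  All spatial
reasoning (stream orders, distance from mouth, focal neighbourhoods) happens
in one-dimensional chainage coordinates along this graph; there is no notion
of geographic position.  Reaches are discretised into fixed-length cells
(nominally 50 m) which play the role of the raster cells of a gridded river
network, and in-river barriers are point features located by edge and
chainage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

__all__ = [
    "Edge",
    "Barrier",
    "NetworkPoint",
    "CellIndex",
    "RiverNetwork",
    "NetworkError",
    "strahler_orders",
    "shreve_orders",
    "distance_from_mouth",
    "discretize",
]

DEFAULT_CELL_LENGTH = 50.0


class NetworkError(ValueError):
    """Raised for structurally invalid networks or off-network points."""


@dataclass(frozen=True)
class Edge:
    edge_id: Hashable
    up_node: Hashable
    down_node: Hashable
    length_m: float


@dataclass(frozen=True)
class Barrier:
    """In-river barrier located by edge and chainage from the upstream end."""

    edge_id: Hashable
    chainage_m: float
    passable: bool = False


@dataclass(frozen=True)
class NetworkPoint:
    """A point on the network: edge plus chainage from the upstream end."""

    edge_id: Hashable
    chainage_m: float


@dataclass(frozen=True)
class CellIndex:
    """One cell of the discretised network.

    Cells tile each edge from its upstream end downstream; the last cell of
    an edge may be shorter than the nominal cell length.
    """

    cell_id: int
    edge_id: Hashable
    index: int
    start_m: float
    end_m: float

    @property
    def center_m(self) -> float:
        return 0.5 * (self.start_m + self.end_m)

    @property
    def length_m(self) -> float:
        return self.end_m - self.start_m


class RiverNetwork:
    """Directed tree of river reaches draining to one outlet.

    Parameters
    ----------
    edges
        Iterable of ``(edge_id, up_node, down_node, length_m)`` tuples or
        :class:`Edge` instances.  Every node must have a unique downstream
        path to the single outlet node (no cycles, no braiding).
    barriers
        Iterable of ``(edge_id, chainage_m, passable)`` tuples or
        :class:`Barrier` instances.
    """

    def __init__(self, edges: Iterable, barriers: Iterable = ()) -> None:
        self.edges: dict[Hashable, Edge] = {}
        for e in edges:
            if not isinstance(e, Edge):
                e = Edge(*e)
            if e.length_m <= 0:
                raise NetworkError(f"edge {e.edge_id!r} has non-positive length")
            if e.edge_id in self.edges:
                raise NetworkError(f"duplicate edge id {e.edge_id!r}")
            self.edges[e.edge_id] = e
        if not self.edges:
            raise NetworkError("network has no edges")

        self._down_edge_of_node: dict[Hashable, Edge] = {}
        nodes: set[Hashable] = set()
        for e in self.edges.values():
            nodes.add(e.up_node)
            nodes.add(e.down_node)
            if e.up_node in self._down_edge_of_node:
                raise NetworkError(
                    f"node {e.up_node!r} has more than one downstream edge (braided network)"
                )
            self._down_edge_of_node[e.up_node] = e

        outlets = [n for n in nodes if n not in self._down_edge_of_node]
        if len(outlets) != 1:
            raise NetworkError(f"expected exactly one outlet node, found {len(outlets)}")
        self.outlet_node = outlets[0]
        if len(self.edges) != len(nodes) - 1:
            raise NetworkError("edge/node count inconsistent with a tree")

        # upstream edges per node (tributaries arriving at that node)
        self._up_edges_of_node: dict[Hashable, list[Edge]] = {}
        for e in self.edges.values():
            self._up_edges_of_node.setdefault(e.down_node, []).append(e)

        # reachability check: walk each node downstream to the outlet
        for n in nodes:
            seen = set()
            cur = n
            while cur != self.outlet_node:
                if cur in seen:
                    raise NetworkError("cycle detected")
                seen.add(cur)
                cur = self._down_edge_of_node[cur].down_node

        self.barriers: list[Barrier] = []
        for b in barriers:
            if not isinstance(b, Barrier):
                b = Barrier(*b)
            edge = self.edges.get(b.edge_id)
            if edge is None:
                raise NetworkError(f"barrier on unknown edge {b.edge_id!r}")
            if not 0.0 <= b.chainage_m <= edge.length_m:
                raise NetworkError(
                    f"barrier chainage {b.chainage_m} outside edge {b.edge_id!r}"
                )
            self.barriers.append(b)

        self._node_dist_to_outlet: dict[Hashable, float] | None = None

    # -- basic topology ----------------------------------------------------

    def tributaries(self, node: Hashable) -> list[Edge]:
        """Edges whose downstream node is ``node``."""
        return list(self._up_edges_of_node.get(node, []))

    def downstream_edge(self, node: Hashable) -> Edge | None:
        return self._down_edge_of_node.get(node)

    def headwater_edges(self) -> list[Edge]:
        return [e for e in self.edges.values() if not self._up_edges_of_node.get(e.up_node)]

    def edges_upstream_order(self) -> list[Edge]:
        """Edges sorted so that tributaries precede the reach they feed."""
        order: list[Edge] = []
        # iterative post-order from the outlet upward
        stack = [e for e in self._up_edges_of_node.get(self.outlet_node, [])]
        visit: list[Edge] = []
        while stack:
            e = stack.pop()
            visit.append(e)
            stack.extend(self._up_edges_of_node.get(e.up_node, []))
        return list(reversed(visit))

    def node_distance_to_outlet(self, node: Hashable) -> float:
        if self._node_dist_to_outlet is None:
            dist: dict[Hashable, float] = {self.outlet_node: 0.0}
            for e in reversed(self.edges_upstream_order()):
                dist[e.up_node] = dist[e.down_node] + e.length_m
            self._node_dist_to_outlet = dist
        return self._node_dist_to_outlet[node]

    def total_length_m(self) -> float:
        return sum(e.length_m for e in self.edges.values())

    def validate_point(self, p: NetworkPoint) -> Edge:
        edge = self.edges.get(p.edge_id)
        if edge is None:
            raise NetworkError(f"point on unknown edge {p.edge_id!r}")
        if not 0.0 <= p.chainage_m <= edge.length_m:
            raise NetworkError(
                f"chainage {p.chainage_m} outside edge {p.edge_id!r} (length {edge.length_m})"
            )
        return edge


def strahler_orders(net: RiverNetwork) -> dict[Hashable, int]:
    """Strahler stream order per edge.

    Headwater edges are order 1.  At a confluence the downstream order is the
    maximum of the tributary orders, incremented by one only if that maximum
    is attained by at least two tributaries; a lower-order stream joining a
    higher-order one leaves the order unchanged.  Confluences with more than
    two tributaries follow the same rule.
    """
    orders: dict[Hashable, int] = {}
    for e in net.edges_upstream_order():
        tribs = net.tributaries(e.up_node)
        if not tribs:
            orders[e.edge_id] = 1
        else:
            vals = [orders[t.edge_id] for t in tribs]
            top = max(vals)
            orders[e.edge_id] = top + 1 if vals.count(top) >= 2 else top
    return orders


def shreve_orders(net: RiverNetwork) -> dict[Hashable, int]:
    """Shreve magnitude per edge: headwaters 1, confluences sum tributaries."""
    orders: dict[Hashable, int] = {}
    for e in net.edges_upstream_order():
        tribs = net.tributaries(e.up_node)
        orders[e.edge_id] = sum(orders[t.edge_id] for t in tribs) if tribs else 1
    return orders


def distance_from_mouth(net: RiverNetwork, p: NetworkPoint) -> float:
    """Along-network distance (m) from a point to the outlet."""
    edge = net.validate_point(p)
    return (edge.length_m - p.chainage_m) + net.node_distance_to_outlet(edge.down_node)


def discretize(net: RiverNetwork, cell_length: float = DEFAULT_CELL_LENGTH) -> list[CellIndex]:
    """Tile every edge upstream-to-downstream into cells of ``cell_length``.

    Each edge gets ``ceil(length / cell_length)`` cells; the terminal cell of
    an edge may be shorter.  Cell ids number the cells consecutively in edge
    insertion order.
    """
    if cell_length <= 0:
        raise ValueError("cell_length must be positive")
    cells: list[CellIndex] = []
    cid = 0
    for e in net.edges.values():
        n = math.ceil(e.length_m / cell_length - 1e-9)
        for i in range(n):
            start = i * cell_length
            end = min((i + 1) * cell_length, e.length_m)
            cells.append(CellIndex(cid, e.edge_id, i, start, end))
            cid += 1
    return cells
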