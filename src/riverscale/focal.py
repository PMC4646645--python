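"""Barrier-aware focal (neighbourhood) statistics on the river network.

For a sampling site and a distance class ``d`` the focal neighbourhood is
the set of grid cells whose along-network distance from the site is at most
``d``, walking both up- and downstream and entering tributary branches, but
never crossing an impassable barrier.  The total river length covered by a
barrier-free neighbourhood on a straight channel is therefore ``2 d`` (e.g.
5000 m for the 2500 m distance class).  The focal value of a habitat
variable is the mean (continuous, count-rate) or the median (ordinal,
score) of the cell values in the neighbourhood; cell values are inherited
from the mapped channel segment containing the cell centre.
"""

from __future__ import annotations

import logging
import math
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import MEAN_KINDS, Catalog
from .network import (
    DEFAULT_CELL_LENGTH,
    CellIndex,
    NetworkError,
    NetworkPoint,
    RiverNetwork,
    discretize,
    distance_from_mouth,
    shreve_orders,
    strahler_orders,
)

log = logging.getLogger(__name__)

DISTANCE_CLASSES = (0.0, 200.0, 1000.0, 2500.0, 4000.0)

__all__ = [
    "DISTANCE_CLASSES",
    "snap_barrier",
    "network_neighborhood",
    "focal_value",
    "build_focal_table",
    "site_topology",
]


def snap_barrier(chainage_m: float, edge_length_m: float, cell_length: float) -> float:
    """Snap a barrier chainage to the nearest cell boundary on its edge."""
    snapped = round(chainage_m / cell_length) * cell_length
    return float(min(max(snapped, 0.0), edge_length_m))


def _split_graph(net: RiverNetwork, cell_length: float) -> tuple[nx.Graph, dict]:
    """Undirected graph of network nodes with edges split at impassable barriers.

    Returns the graph and, per edge id, the list of sub-edges as
    ``(node_a, node_b, chain_lo, chain_hi)`` with ``node_a`` at ``chain_lo``.
    Barriers are snapped to cell boundaries; the two flanking sub-edges share
    no node, which is what truncates traversal.
    """
    g = nx.Graph()
    pieces: dict[Hashable, list[tuple]] = {}
    cuts: dict[Hashable, set[float]] = {}
    for b in net.barriers:
        if b.passable:
            continue
        edge = net.edges[b.edge_id]
        c = snap_barrier(b.chainage_m, edge.length_m, cell_length)
        cuts.setdefault(b.edge_id, set()).add(c)

    for e in net.edges.values():
        ecuts = cuts.get(e.edge_id, set())
        # a cut snapped onto an edge end severs the edge from that node
        start_node = ("__cut0", e.edge_id) if 0.0 in ecuts else e.up_node
        final_node = ("__cutL", e.edge_id) if e.length_m in ecuts else e.down_node
        interior = sorted(c for c in ecuts if 0.0 < c < e.length_m)
        bounds = [0.0] + interior + [e.length_m]
        subs = []
        prev_node = start_node
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            last = k == len(bounds) - 2
            # the two sides of a cut get distinct, unconnected nodes
            end_node = final_node if last else ("__barL", e.edge_id, k)
            g.add_node(prev_node)
            g.add_node(end_node)
            g.add_edge(prev_node, end_node, weight=hi - lo)
            subs.append((prev_node, end_node, lo, hi))
            prev_node = ("__barR", e.edge_id, k)
        pieces[e.edge_id] = subs
        g.add_node(e.up_node)
        g.add_node(e.down_node)
    return g, pieces


def _site_cell(cells_by_edge: dict, p: NetworkPoint, cell_length: float) -> CellIndex:
    cells = cells_by_edge[p.edge_id]
    idx = min(int(p.chainage_m // cell_length), len(cells) - 1)
    return cells[idx]


def network_neighborhood(
    net: RiverNetwork,
    site: NetworkPoint,
    d: float,
    cells: Sequence[CellIndex] | None = None,
    cell_length: float = DEFAULT_CELL_LENGTH,
    updown_strict: bool = False,
) -> list[CellIndex]:
    """Cells within network distance ``d`` of a site, truncated at barriers.

    Distances are measured between cell centres; the site is snapped to the
    centre of the cell containing it, so ``d = 0`` returns exactly that cell.
    Traversal is undirected by default: beyond a downstream confluence the
    other tributary's cells are admitted within the remaining distance.  With
    ``updown_strict`` only cells strictly upstream of the site (its upstream
    subtree) or on its direct downstream path are eligible.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    net.validate_point(site)
    if cells is None:
        cells = discretize(net, cell_length)
    cells_by_edge: dict[Hashable, list[CellIndex]] = {}
    for c in cells:
        cells_by_edge.setdefault(c.edge_id, []).append(c)

    own = _site_cell(cells_by_edge, site, cell_length)
    if d == 0:
        return [own]

    g, pieces = _split_graph(net, cell_length)
    site_pos = own.center_m

    def piece_of(edge_id, chain):
        # cell centres lie strictly inside a piece (cuts sit on cell boundaries)
        for sub in pieces[edge_id]:
            if sub[2] - 1e-9 <= chain <= sub[3] + 1e-9:
                return sub
        raise NetworkError("chainage outside edge pieces")

    sa, sb, slo, shi = piece_of(site.edge_id, site_pos)
    g.add_node("__site")
    g.add_edge("__site", sa, weight=site_pos - slo)
    g.add_edge("__site", sb, weight=shi - site_pos)
    dist = nx.single_source_dijkstra_path_length(g, "__site", cutoff=d + cell_length)
    g.remove_node("__site")

    allowed: set[Hashable] | None = None
    if updown_strict:
        allowed = _strict_edges(net, site.edge_id)

    out: list[CellIndex] = []
    for c in cells:
        if allowed is not None and c.edge_id not in allowed:
            continue
        if c.edge_id == own.edge_id and c.index == own.index:
            out.append(c)
            continue
        a, b, lo, hi = piece_of(c.edge_id, c.center_m)
        best = math.inf
        if (c.edge_id, a, b) == (site.edge_id, sa, sb):
            best = abs(c.center_m - site_pos)
        if a in dist:
            best = min(best, dist[a] + (c.center_m - lo))
        if b in dist:
            best = min(best, dist[b] + (hi - c.center_m))
        if best <= d + 1e-6:
            out.append(c)
    return out


def _strict_edges(net: RiverNetwork, site_edge: Hashable) -> set[Hashable]:
    """Edges upstream of the site edge, the site edge, and its downstream path."""
    allowed = {site_edge}
    # upstream subtree
    stack = [net.edges[site_edge]]
    while stack:
        e = stack.pop()
        for t in net.tributaries(e.up_node):
            allowed.add(t.edge_id)
            stack.append(t)
    # downstream path
    e = net.edges[site_edge]
    while True:
        nxt = net.downstream_edge(e.down_node)
        if nxt is None:
            break
        allowed.add(nxt.edge_id)
        e = nxt
    return allowed


def focal_value(values, kind: str) -> float:
    """Summarise a neighbourhood: mean for continuous/count-rate variables,
    lower-middle-order-statistic median for ordinal/score variables."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    if kind in MEAN_KINDS:
        return float(arr.mean())
    arr.sort()
    return float(arr[(arr.size - 1) // 2])


class SegmentLocator:
    """Maps cells to the segment row whose chainage span contains the centre."""

    def __init__(self, segments: pd.DataFrame) -> None:
        self._by_edge: dict[Hashable, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for edge_id, grp in segments.groupby("edge_id", sort=False):
            grp = grp.sort_values("start_m")
            self._by_edge[edge_id] = (
                grp["start_m"].to_numpy(),
                grp["end_m"].to_numpy(),
                grp.index.to_numpy(),
            )

    def row_for(self, cell: CellIndex):
        entry = self._by_edge.get(cell.edge_id)
        if entry is None:
            return None
        starts, ends, idx = entry
        i = np.searchsorted(starts, cell.center_m, side="right") - 1
        if i < 0 or cell.center_m > ends[i] + 1e-9:
            return None
        return idx[i]


def build_focal_table(
    net: RiverNetwork,
    segments: pd.DataFrame,
    sites: pd.DataFrame,
    catalog: Catalog,
    distances: Iterable[float] = DISTANCE_CLASSES,
    cell_length: float = DEFAULT_CELL_LENGTH,
    updown_strict: bool = False,
    focal_topo: bool = False,
) -> pd.DataFrame:
    """Focal predictor table: one value per (site, variable, distance class).

    ``segments`` holds one row per mapped channel segment (``edge_id``,
    ``start_m``, ``end_m`` plus one column per variable code); ``sites`` has
    ``site_id``, ``edge_id``, ``chainage_m``.  Topological variables are
    site-level attributes of the network and by default are not focally
    averaged (``focal_topo`` enables averaging them like any other column if
    they are present in ``segments``).

    Returns a long table ``site_id, variable, distance_m, value``.
    Missing cell values are dropped from the statistic; all-missing
    neighbourhoods propagate NaN and are logged.
    """
    var_cols = [c for c in segments.columns if c not in ("edge_id", "start_m", "end_m")]
    unknown = [c for c in var_cols if c not in catalog]
    if unknown:
        raise KeyError(f"segment table has variable codes not in the catalogue: {unknown}")
    if not focal_topo:
        var_cols = [c for c in var_cols if catalog[c].set != "topological"]
    kinds = {c: catalog[c].kind for c in var_cols}

    cells = discretize(net, cell_length)
    locator = SegmentLocator(segments)
    cell_rows = {(c.edge_id, c.index): locator.row_for(c) for c in cells}
    values = segments[var_cols]

    records = []
    n_missing = 0
    for s in sites.itertuples(index=False):
        point = NetworkPoint(s.edge_id, float(s.chainage_m))
        for d in distances:
            hood = network_neighborhood(
                net, point, float(d), cells=cells, cell_length=cell_length,
                updown_strict=updown_strict,
            )
            rows = [cell_rows[(c.edge_id, c.index)] for c in hood]
            rows = [r for r in rows if r is not None]
            if not rows:
                for v in var_cols:
                    records.append((s.site_id, v, float(d), math.nan))
                n_missing += len(var_cols)
                continue
            sub = values.loc[rows]
            for v in var_cols:
                val = focal_value(sub[v].to_numpy(), kinds[v])
                if math.isnan(val):
                    n_missing += 1
                records.append((s.site_id, v, float(d), val))
    if n_missing:
        log.warning("focal table: %d all-missing (site, variable, distance) entries", n_missing)
    return pd.DataFrame(records, columns=["site_id", "variable", "distance_m", "value"])


def site_topology(net: RiverNetwork, sites: pd.DataFrame) -> pd.DataFrame:
    """Topological variables evaluated at each site.

    ``DisM`` is the along-network distance from the site to the outlet;
    ``SOSh``/``SOSt`` are the Shreve and Strahler orders of the site's reach.
    """
    strahler = strahler_orders(net)
    shreve = shreve_orders(net)
    rows = []
    for s in sites.itertuples(index=False):
        p = NetworkPoint(s.edge_id, float(s.chainage_m))
        rows.append(
            (s.site_id, distance_from_mouth(net, p), shreve[s.edge_id], strahler[s.edge_id])
        )
    return pd.DataFrame(rows, columns=["site_id", "DisM", "SOSh", "SOSt"]).set_index("site_id")
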