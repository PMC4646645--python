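import math

import numpy as np
import pandas as pd
import pytest

from riverscale.catalog import load_catalog
from riverscale.focal import (
    build_focal_table,
    focal_value,
    network_neighborhood,
    site_topology,
)
from riverscale.network import Barrier, Edge, NetworkError, NetworkPoint, RiverNetwork, discretize

from conftest import brute_neighborhood, random_tree

CATALOG = load_catalog()


def straight_river(length=10000.0):
    return RiverNetwork([("main", "top", "out", length)])


class TestNeighborhood:
    def test_zero_distance_is_own_cell(self):
        net = straight_river()
        hood = network_neighborhood(net, NetworkPoint("main", 5010), 0)
        assert len(hood) == 1
        assert (hood[0].edge_id, hood[0].index) == ("main", 100)

    def test_straight_river_spans_twice_the_distance(self):
        # the reach covered by a barrier-free neighbourhood is 2 d in total
        net = straight_river()
        site = NetworkPoint("main", 5000)
        hood = network_neighborhood(net, site, 2500)
        centers = [c.center_m for c in hood]
        assert max(centers) - min(centers) == pytest.approx(5000)
        assert sum(c.length_m for c in hood) == pytest.approx(5000 + 50)

    def test_upstream_barrier_truncates_one_side(self):
        net = RiverNetwork([("main", "top", "out", 10000)], [("main", 4900, False)])
        site = NetworkPoint("main", 5000)
        hood = network_neighborhood(net, site, 1000)
        centers = [c.center_m for c in hood]
        assert min(centers) == 4925  # nothing above the barrier at 4900
        assert max(centers) == 6025  # full 1000 m downstream

    def test_passable_barrier_does_not_truncate(self):
        net = RiverNetwork([("main", "top", "out", 10000)], [("main", 4900, True)])
        hood = network_neighborhood(net, NetworkPoint("main", 5000), 1000)
        assert min(c.center_m for c in hood) == 4025

    def test_tributary_included_beyond_downstream_confluence(self):
        net = RiverNetwork(
            [("a", "u1", "c", 500), ("b", "u2", "c", 500), ("s", "c", "o", 500)]
        )
        hood = network_neighborhood(net, NetworkPoint("a", 400), 300)
        edges = {c.edge_id for c in hood}
        assert edges == {"a", "b", "s"}

    def test_strict_mode_excludes_sibling_tributary(self):
        net = RiverNetwork(
            [("a", "u1", "c", 500), ("b", "u2", "c", 500), ("s", "c", "o", 500)]
        )
        hood = network_neighborhood(net, NetworkPoint("a", 400), 300, updown_strict=True)
        assert {c.edge_id for c in hood} == {"a", "s"}

    def test_monotone_in_distance_and_barriers(self, rng):
        for _ in range(20):
            net = random_tree(rng, int(rng.integers(3, 20)), barrier_prob=0.3)
            eid = list(net.edges)[int(rng.integers(len(net.edges)))]
            site = NetworkPoint(eid, net.edges[eid].length_m / 2)
            prev: set = set()
            for d in (0, 150, 400, 900):
                hood = {(c.edge_id, c.index) for c in network_neighborhood(net, site, d)}
                assert prev <= hood
                prev = hood
            free = RiverNetwork(list(net.edges.values()))  # barriers removed
            hood_free = {(c.edge_id, c.index) for c in network_neighborhood(free, site, 900)}
            assert prev <= hood_free

    def test_matches_cell_graph_oracle(self, rng):
        """Neighbourhoods equal exhaustive path enumeration on the cell graph."""
        for _ in range(100):
            net = random_tree(rng, int(rng.integers(2, 31)), barrier_prob=0.4)
            eid = list(net.edges)[int(rng.integers(len(net.edges)))]
            site = NetworkPoint(eid, float(rng.uniform(0, net.edges[eid].length_m)))
            d = float(rng.uniform(0, 1500))
            got = {(c.edge_id, c.index) for c in network_neighborhood(net, site, d)}
            assert got == brute_neighborhood(net, site, d, 50.0)

    def test_off_network_site_rejected(self):
        with pytest.raises(NetworkError):
            network_neighborhood(straight_river(), NetworkPoint("x", 0), 100)


class TestFocalValue:
    @pytest.mark.parametrize("kind", ["continuous", "ordinal", "score", "count_rate"])
    def test_constant_input_returns_constant(self, kind):
        assert focal_value([3, 3, 3], kind) == 3

    def test_mean_for_continuous(self):
        assert focal_value([0, 0, 1, 1], "continuous") == 0.5

    def test_lower_middle_median_for_ordinal(self):
        # even count: lower middle order statistic keeps the ordinal scale
        assert focal_value([1, 2, 2, 5], "ordinal") == 2
        assert focal_value([5, 1, 2, 2], "ordinal") == 2
        assert focal_value([1, 4], "score") == 1

    def test_missing_dropped_then_nan(self):
        assert focal_value([math.nan, 2.0], "continuous") == 2.0
        assert math.isnan(focal_value([math.nan], "continuous"))


def segments_for(net, value_map):
    """One 100 m-segment table; value_map: code -> callable(edge_id, start)."""
    rows = []
    for e in net.edges.values():
        n = math.ceil(e.length_m / 100 - 1e-9)
        for i in range(n):
            start, end = i * 100.0, min((i + 1) * 100.0, e.length_m)
            rows.append({"edge_id": e.edge_id, "start_m": start, "end_m": end,
                         **{k: f(e.edge_id, start) for k, f in value_map.items()}})
    return pd.DataFrame(rows)


class TestFocalTable:
    def test_homogeneous_network_constant_over_distance(self, rng):
        net = random_tree(rng, 10)
        segs = segments_for(net, {"ChDe": lambda e, s: 0.7, "FlVe": lambda e, s: 3})
        sites = pd.DataFrame({"site_id": ["s1"], "edge_id": [list(net.edges)[0]],
                              "chainage_m": [30.0]})
        tab = build_focal_table(net, segs, sites, CATALOG, distances=(0, 200, 1000))
        assert len(tab) == 2 * 3
        assert tab[tab.variable == "ChDe"].value.to_numpy() == pytest.approx(0.7)
        assert (tab[tab.variable == "FlVe"].value == 3).all()

    def test_step_variable_averages_to_half(self):
        # variable 1 upstream of the site, 0 downstream, symmetric coverage
        net = straight_river(10000)
        segs = segments_for(net, {"SuSa": lambda e, s: 100.0 if s < 5000 else 0.0})
        sites = pd.DataFrame({"site_id": ["s1"], "edge_id": ["main"], "chainage_m": [5000.0]})
        tab = build_focal_table(net, segs, sites, CATALOG, distances=(2000,))
        # site cell center is at 5025 (inside the 0 block); neighbourhood spans
        # [3025, 7025] -> 40 cells at 100, 41 at 0
        val = tab.value.iloc[0]
        assert val == pytest.approx(100 * 40 / 81)

    def test_zero_distance_equals_site_segment_value(self, rng):
        net = random_tree(rng, 8)
        segs = segments_for(net, {"ChWi": lambda e, s: hash((e, s)) % 50 + 1.0})
        eid = list(net.edges)[3]
        sites = pd.DataFrame({"site_id": ["s"], "edge_id": [eid], "chainage_m": [10.0]})
        tab = build_focal_table(net, segs, sites, CATALOG, distances=(0,))
        expected = segs[(segs.edge_id == eid) & (segs.start_m == 0)]["ChWi"].iloc[0]
        assert tab.value.iloc[0] == expected

    def test_unknown_variable_code_rejected(self):
        net = straight_river(1000)
        segs = segments_for(net, {"NotAVar": lambda e, s: 1.0})
        sites = pd.DataFrame({"site_id": ["s"], "edge_id": ["main"], "chainage_m": [10.0]})
        with pytest.raises(KeyError, match="NotAVar"):
            build_focal_table(net, segs, sites, CATALOG)

    def test_focal_mean_bounded_by_cell_values(self, rng):
        net = random_tree(rng, 12, barrier_prob=0.3)
        segs = segments_for(net, {"SuHa": lambda e, s: float(abs(hash((e, s))) % 100)})
        eid = list(net.edges)[0]
        sites = pd.DataFrame({"site_id": ["s"], "edge_id": [eid], "chainage_m": [5.0]})
        tab = build_focal_table(net, segs, sites, CATALOG, distances=(0, 500, 1500))
        assert tab.value.between(segs.SuHa.min(), segs.SuHa.max()).all()


class TestSiteTopology:
    def test_orders_and_distance_at_sites(self):
        net = RiverNetwork(
            [("a", "u1", "c", 500), ("b", "u2", "c", 600), ("s", "c", "o", 700)]
        )
        sites = pd.DataFrame(
            {"site_id": ["x", "y"], "edge_id": ["a", "s"], "chainage_m": [100.0, 200.0]}
        )
        topo = site_topology(net, sites)
        assert topo.loc["x", "SOSt"] == 1 and topo.loc["y", "SOSt"] == 2
        assert topo.loc["x", "SOSh"] == 1 and topo.loc["y", "SOSh"] == 2
        assert topo.loc["x", "DisM"] == 400 + 700
        assert topo.loc["y", "DisM"] == 500
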