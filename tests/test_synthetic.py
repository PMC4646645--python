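import numpy as np
import pandas as pd
import pytest

from riverscale.catalog import load_catalog
from riverscale.focal import build_focal_table
from riverscale.network import NetworkPoint
from riverscale.synthetic import (
    SyntheticConfig,
    gen_habitat,
    gen_network,
    gen_sites,
    gen_virtual_species,
    published_auc_table,
)

CATALOG = load_catalog()

SMALL = SyntheticConfig(seed=9, n_headwaters=12, mean_edge_length_m=900.0,
                        n_sites=20, n_species=3)


class TestGenNetwork:
    def test_single_headwater_is_a_chain(self):
        net = gen_network(SyntheticConfig(seed=1, n_headwaters=1))
        assert len(net.edges) == 1

    def test_edge_count_and_determinism(self):
        a = gen_network(SMALL)
        b = gen_network(SMALL)
        assert len(a.edges) == 2 * SMALL.n_headwaters - 1
        assert [(e.edge_id, e.length_m) for e in a.edges.values()] == [
            (e.edge_id, e.length_m) for e in b.edges.values()
        ]
        assert [(x.edge_id, x.chainage_m, x.passable) for x in a.barriers] == [
            (x.edge_id, x.chainage_m, x.passable) for x in b.barriers
        ]

    def test_barrier_density_matches_config(self):
        dens = []
        for s in range(60):
            net = gen_network(SyntheticConfig(seed=s, n_headwaters=20))
            dens.append(len(net.barriers) / (net.total_length_m() / 1000))
        assert np.mean(dens) == pytest.approx(0.16, rel=0.10)


@pytest.fixture(scope="module")
def study():
    net = gen_network(SMALL)
    return net, gen_habitat(net, SMALL, CATALOG)


class TestGenHabitat:
    def test_category_bounds_respected(self, study):
        _, segs = study
        for code in ("FlVe", "Plan", "FE-Pla", "BPno"):
            v = CATALOG[code]
            assert segs[code].between(v.cat_min, v.cat_max).all()
            assert (segs[code] == segs[code].astype(int)).all()

    def test_counts_and_percentages_nonnegative(self, study):
        _, segs = study
        for code in ("BAEr", "CBFR", "SuSa", "SuSo", "ChWi"):
            assert (segs[code] >= 0).all()

    def test_autocorrelation_decays_with_network_distance(self):
        cfg = SyntheticConfig(seed=5, n_headwaters=8, mean_edge_length_m=3000.0,
                              autocorr_range_m=800.0)
        net = gen_network(cfg)
        segs = gen_habitat(net, cfg, CATALOG)
        # within-edge lag-1 (100 m) vs lag-10 (1000 m) correlation of a
        # continuous field
        x = segs.sort_values(["edge_id", "start_m"])
        vals, short, long = [], [], []
        for _, grp in x.groupby("edge_id"):
            v = grp["SuSa"].to_numpy()
            if len(v) > 12:
                short.append(np.column_stack([v[:-1], v[1:]]))
                long.append(np.column_stack([v[:-10], v[10:]]))
        short, long = np.vstack(short), np.vstack(long)
        r_short = np.corrcoef(short.T)[0, 1]
        r_long = np.corrcoef(long.T)[0, 1]
        assert r_short > 0.6  # exp(-100/800) = 0.88 in the latent field
        assert r_long < r_short
        assert r_long < 0.5  # exp(-1000/800) = 0.29

    def test_tiny_range_gives_uncorrelated_neighbours(self):
        cfg = SyntheticConfig(seed=6, n_headwaters=8, mean_edge_length_m=3000.0,
                              autocorr_range_m=1e-6)
        net = gen_network(cfg)
        segs = gen_habitat(net, cfg, CATALOG)
        x = segs.sort_values(["edge_id", "start_m"])
        pairs = []
        for _, grp in x.groupby("edge_id"):
            v = grp["SuSa"].to_numpy()
            pairs.append(np.column_stack([v[:-1], v[1:]]))
        pairs = np.vstack(pairs)
        assert abs(np.corrcoef(pairs.T)[0, 1]) < 0.2

    def test_longitudinal_gradient_variable_tracks_distance_from_mouth(self, study):
        net, segs = study
        from riverscale.network import distance_from_mouth

        dism = np.array([
            distance_from_mouth(net, NetworkPoint(r.edge_id, 0.5 * (r.start_m + r.end_m)))
            for r in segs.itertuples(index=False)
        ])
        r = np.corrcoef(dism, segs["ChWi"])[0, 1]
        assert r < -0.3  # channels widen downstream


class TestVirtualSpecies:
    def test_deterministic_and_schema(self):
        net = gen_network(SMALL)
        segs = gen_habitat(net, SMALL, CATALOG)
        sites = gen_sites(net, SMALL)
        a = gen_virtual_species(net, segs, sites, SMALL, CATALOG)
        b = gen_virtual_species(net, segs, sites, SMALL, CATALOG)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.columns) == ["site_id", "species", "year", "count"]
        assert a.species.nunique() == SMALL.n_species

    def test_null_effects_give_half_prevalence(self):
        cfg = SyntheticConfig(seed=3, n_headwaters=40, n_sites=64, n_species=20,
                              effect_size_range=(0.0, 0.0), prevalence_range=(0.5, 0.5))
        net = gen_network(cfg)
        segs = gen_habitat(net, cfg, CATALOG)
        sites = gen_sites(net, cfg)
        rec = gen_virtual_species(net, segs, sites, cfg, CATALOG)
        prev = rec.groupby("species")["count"].apply(lambda c: (c > 0).mean() * 2)
        assert prev.mean() == pytest.approx(0.5, abs=0.06)

    def test_huge_effects_saturate_probabilities(self):
        cfg = SyntheticConfig(seed=4, n_headwaters=20, n_sites=30, n_species=4,
                              effect_size_range=(100.0, 120.0))
        net = gen_network(cfg)
        segs = gen_habitat(net, cfg, CATALOG)
        sites = gen_sites(net, cfg)
        a = gen_virtual_species(net, segs, sites, cfg, CATALOG)
        # occurrence is then a deterministic function of habitat: rerunning
        # with a different Bernoulli stream would change nothing, so the two
        # survey years agree exactly with the habitat threshold rule
        pres = a.groupby(["species", "site_id"])["count"].max()
        assert set(pres.unique()) <= set(range(0, 20))

    def test_scale_signal_recoverable_by_logistic_fit(self):
        """Deviance explained is higher at the true 2500 m scale than at 0 m."""
        from sklearn.linear_model import LogisticRegression

        wins = 0
        for s in (1, 2, 3, 4, 5):
            cfg = SyntheticConfig(seed=s, n_headwaters=40, n_sites=60, n_species=3)
            net = gen_network(cfg)
            segs = gen_habitat(net, cfg, CATALOG)
            sites = gen_sites(net, cfg)
            rec = gen_virtual_species(net, segs, sites, cfg, CATALOG)
            focal = build_focal_table(
                net, segs[["edge_id", "start_m", "end_m", *cfg.effect_vars]],
                sites, CATALOG, distances=(0.0, 2500.0),
            )
            pres = rec.groupby(["species", "site_id"])["count"].max().gt(0).astype(int)
            scores = {}
            for d in (0.0, 2500.0):
                X = focal[focal.distance_m == d].pivot_table(
                    index="site_id", columns="variable", values="value"
                ).reindex(sites.site_id)
                Xz = ((X - X.mean()) / X.std()).fillna(0.0).to_numpy()
                ll = 0.0
                for sp in rec.species.unique():
                    y = pres[sp].reindex(sites.site_id).to_numpy()
                    if y.sum() in (0, len(y)):
                        continue
                    m = LogisticRegression(C=1.0).fit(Xz, y)
                    p = np.clip(m.predict_proba(Xz)[:, 1], 1e-9, 1 - 1e-9)
                    ll += np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
                scores[d] = ll
            wins += scores[2500.0] > scores[0.0]
        assert wins >= 4


class TestFixture:
    def test_shape_and_flags(self):
        t3 = published_auc_table()
        assert len(t3) == 260
        assert t3.converged.sum() == 258
        failed = t3[~t3.converged]
        assert set(zip(failed.species, failed.varset, failed.distance_m)) == {
            ("Tincinca", "MV", 2500), ("Gastatus", "AV", 0)
        }
        assert (failed.topo == "no").all()

    def test_published_summary_statistics(self):
        t3 = published_auc_table()
        ok = t3[t3.converged]
        assert ok.auc.mean() == pytest.approx(0.782, abs=0.001)
        cell = t3[(t3.species == "Gobiobio") & (t3.varset == "MV")
                  & (t3.distance_m == 0) & (t3.topo == "no")]
        assert cell.auc.iloc[0] == 0.94
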