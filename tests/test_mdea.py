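import itertools
import math

import networkx as nx
import numpy as np
import pytest

from mdinet.formulas import default_building_blocks, parse_formula
from mdinet.mdea import mdea, z_to_p
from mdinet.network import MassDiffNetwork, build_network
from mdinet.simulate import SimulationConfig, generate_metabolome


def _net_from_edges(edges):
    g = nx.MultiGraph()
    for u, v, k in edges:
        g.add_edge(u, v, key=k, ppm_error=0.0, delta=parse_formula("CH2"))
    return MassDiffNetwork(g)


def hypergeom_tail(a, N, K, n):
    """Exhaustive enumeration of P(X >= a) for X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(a, min(K, n) + 1)) / total


class TestZtoP:
    def test_zero(self):
        assert z_to_p(0.0) == 1.0

    def test_z2_rounds_to_five_percent(self):
        assert z_to_p(2.0) == pytest.approx(0.0455, abs=1e-4)
        assert round(z_to_p(2.0), 2) == 0.05

    def test_z25_rounds_to_one_percent(self):
        assert z_to_p(2.5) == pytest.approx(0.0124, abs=1e-4)
        assert round(z_to_p(2.5), 2) == 0.01

    def test_symmetry(self):
        assert z_to_p(-1.7) == z_to_p(1.7)


class TestMdea:
    def test_hand_built_ten_edge_network(self):
        """6 CH2 edges all touching markers, 4 O edges touching none:
        one-sided Fisher p = 1/C(10,6) = 1/210."""
        edges = [(f"m{i}", f"x{i}", "CH2") for i in range(6)]
        edges += [(f"y{i}", f"z{i}", "O") for i in range(4)]
        net = _net_from_edges(edges)
        res = mdea(net, {f"m{i}" for i in range(6)}).set_index("block")
        row = res.loc["CH2"]
        assert (row.a, row.b, row.c, row.d) == (6, 0, 0, 4)
        assert row.p_fisher == pytest.approx(1 / 210, rel=1e-9)
        assert row.z > 0

    def test_degenerate_margins(self):
        # every edge same block and every edge touches a marker
        edges = [(f"m{i}", f"x{i}", "CH2") for i in range(5)]
        net = _net_from_edges(edges)
        res = mdea(net, {f"m{i}" for i in range(5)}).set_index("block")
        assert res.loc["CH2", "z"] == 0.0
        assert res.loc["CH2", "p_fisher"] == 1.0

    def test_zero_edge_block_row(self):
        edges = [("m0", "x0", "CH2")]
        cat = default_building_blocks()
        res = mdea(_net_from_edges(edges), {"m0"}, catalogue=cat).set_index("block")
        row = res.loc["H2O"]
        assert (row.a, row.b) == (0, 0)
        assert row.p_fisher == 1.0 and row.z == 0.0

    def test_counts_partition_all_edges(self):
        rng = np.random.default_rng(0)
        edges = [(f"n{rng.integers(12)}", f"n{12 + rng.integers(12)}",
                  rng.choice(["CH2", "O", "H2O"])) for _ in range(30)]
        net = _net_from_edges(edges)
        nodes = sorted(net.graph.nodes)
        res = mdea(net, set(nodes[:3]))
        assert ((res.a + res.b + res.c + res.d) == net.n_edges).all()

    def test_fisher_matches_exhaustive_enumeration(self):
        """On networks with <= 25 edges the Fisher p equals the explicit
        hypergeometric tail sum for every block."""
        rng = np.random.default_rng(1)
        for rep in range(10):
            n_edges = int(rng.integers(5, 26))
            nodes = [f"n{i}" for i in range(10)]
            edges = []
            for _ in range(n_edges):
                u, v = rng.choice(10, 2, replace=False)
                edges.append((nodes[u], nodes[v],
                              str(rng.choice(["CH2", "O", "CO2"]))))
            net = _net_from_edges(edges)
            present = sorted(net.graph.nodes)
            markers = set(rng.choice(present, 3, replace=False))
            res = mdea(net, markers)
            kept = net.edge_table()   # duplicate (u, v, block) rows collapse
            touches = [int(u in markers or v in markers)
                       for u, v in zip(kept.source, kept.target)]
            n_touch = sum(touches)
            N = len(kept)
            for _, row in res.iterrows():
                K = row.a + row.b
                if K == 0 or n_touch in (0, N) or K == N:
                    continue
                assert row.p_fisher == pytest.approx(
                    hypergeom_tail(int(row.a), N, int(K), n_touch), rel=1e-9)

    def test_z_sign_tracks_enrichment_direction(self):
        rng = np.random.default_rng(2)
        edges = [(f"m{i}", f"x{i}", "CH2") for i in range(8)]
        edges += [(f"y{i}", f"z{i}", "O") for i in range(8)]
        net = _net_from_edges(edges)
        res = mdea(net, {f"m{i}" for i in range(8)}).set_index("block")
        assert res.loc["CH2", "z"] > 0 > res.loc["O", "z"]
        assert res.loc["CH2", "p_fisher"] < res.loc["O", "p_fisher"]

    def test_touch_rule_one_versus_any(self):
        edges = [("m0", "m1", "CH2"), ("m0", "x0", "O")]
        net = _net_from_edges(edges)
        any_rule = mdea(net, {"m0", "m1"}).set_index("block")
        one_rule = mdea(net, {"m0", "m1"}, touch_rule="one").set_index("block")
        assert any_rule.loc["CH2", "a"] == 1
        assert one_rule.loc["CH2", "a"] == 0      # marker-marker edge excluded
        assert one_rule.loc["O", "a"] == 1

    def test_markers_outside_network_rejected(self):
        net = _net_from_edges([("a", "b", "CH2")])
        with pytest.raises(ValueError):
            mdea(net, {"zz"})

    def test_false_enrichment_rate_under_random_markers(self):
        """Random marker sets produce p < 0.05 in roughly 5% of blocks."""
        cfg = SimulationConfig(seed=31, n_metabolites=150, n_differential=0)
        gt = generate_metabolome(cfg)
        order = np.argsort(gt.neutral_masses)
        ids = [f"F{i}" for i in range(gt.n)]
        net = build_network(ids, gt.neutral_masses[order],
                            default_building_blocks(), tol_ppm=1.0)
        hits = trials = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            markers = set(rng.choice(ids, 20, replace=False))
            res = mdea(net, markers)
            informative = res[(res.a + res.b) > 0]
            hits += (informative.p_fisher < 0.05).sum()
            trials += len(informative)
        rate = hits / trials
        assert 0.0 <= rate < 0.10

    def test_planted_enriched_block_ranks_first(self):
        """With the enriched-block plan at multiplier 3, the planted block
        tops the Z ranking for the true differential markers in >= 90% of
        seeds."""
        first = 0
        n_seeds = 15
        for s in range(n_seeds):
            cfg = SimulationConfig(seed=s, n_metabolites=150,
                                   n_differential=15,
                                   enriched_blocks=("CO2",),
                                   enrichment_multiplier=3.0)
            gt = generate_metabolome(cfg)
            order = np.argsort(gt.neutral_masses)
            ids = [f"F{i}" for i in range(gt.n)]
            net = build_network(ids, gt.neutral_masses[order],
                                default_building_blocks(), tol_ppm=1.0)
            pos = {k: ids[np.searchsorted(gt.neutral_masses[order],
                                          gt.neutral_masses[k])]
                   for k in gt.differential}
            res = mdea(net, set(pos.values()))
            first += res.iloc[0]["block"] == "CO2"
        assert first / n_seeds >= 0.9
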