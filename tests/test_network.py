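import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microdepth import (CountTable, ValidationError, build_network,
                        compare_networks, detect_modules, fdr_bh,
                        filter_for_network, network_metrics, spearman_matrix,
                        zi_pi)
from microdepth.network import adjusted_p_matrix, topology_frame


def _table(rows, ids=None, asvs=None):
    rows = np.asarray(rows)
    return CountTable(ids or [f"s{i}" for i in range(rows.shape[0])],
                      asvs or [f"a{j}" for j in range(rows.shape[1])], rows)


class TestFilter:
    def test_threshold_and_occurrence_rules(self):
        # 4 samples; a0 at 0.6% present 3/4; a1 at 0.6% present 2/4 (==50%)
        total = 40_000
        counts = np.zeros((4, 3), dtype=int)
        counts[:3, 0] = [80, 80, 80]          # 240/40000 = 0.6%, occ 3/4
        counts[:2, 1] = [120, 120]            # 0.6%, occ 2/4 -> dropped
        counts[:, 2] = (total - counts[:, :2].sum()) // 4  # filler
        t = _table(counts)
        kept = filter_for_network(t, 5e-3, 0.5)
        assert "a0" in kept.asv_ids and "a1" not in kept.asv_ids

    def test_by_hand_survivor_set(self):
        counts = np.array([
            [50, 500, 0, 30, 420],
            [60, 480, 0, 0, 460],
            [40, 520, 5, 0, 435],
            [55, 0, 5, 0, 440],
        ])
        t = _table(counts)
        # totals: a0=205(5.9%) occ 4/4 keep; a1=1500 occ 3/4 keep;
        # a2=10(0.3%) drop; a3=30 occ 1/4 drop; a4 keep
        kept = filter_for_network(t, 5e-3, 0.5)
        assert kept.asv_ids == ["a0", "a1", "a4"]

    def test_nothing_survives_reports_counts(self):
        t = _table(np.array([[1, 1], [1, 1]]))
        with pytest.raises(ValidationError, match="abundance"):
            filter_for_network(t, 0.9, 0.5)


class TestSpearman:
    def test_rank_formula_triple(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) on ties-free ranks
        t = _table(np.array([[1, 3], [2, 1], [3, 2]]), ids=["s1", "s2", "s3"])
        t = CountTable(t.sample_ids + ["s4"], t.asv_ids,
                       np.vstack([t.counts, [[4, 4]]]))
        rho, p = spearman_matrix(t)
        # ranks x: 1,2,3,4; y: 3,1,2,4 -> d^2 = 4+1+1+0 = 6 -> 1 - 36/60
        assert rho.iloc[0, 1] == pytest.approx(1 - 6 * 6 / (4 * 15))

    def test_monotone_perfect_correlation(self):
        t = _table(np.array([[1, 10], [2, 20], [5, 21], [9, 40]]))
        rho, p = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert p.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 30, size=(10, 6)))
        rho, p = spearman_matrix(t)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_constant_asv_flagged(self):
        t = _table(np.array([[5, 1], [5, 2], [5, 3], [5, 9]]))
        rho, p = spearman_matrix(t)
        assert np.isnan(p.iloc[0, 1])
        assert rho.iloc[0, 0] == 1.0


class TestFdrBH:
    def test_step_up_hand_examples(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(fdr_bh([0.005, 0.049, 0.05]),
                                   [0.015, 0.05, 0.05])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.2])


class TestBuildNetwork:
    def _mats(self, rho_ab, q_ab):
        ids = ["a", "b", "c"]
        rho = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        q = pd.DataFrame(np.ones((3, 3)), index=ids, columns=ids)
        rho.iloc[0, 1] = rho.iloc[1, 0] = rho_ab
        q.iloc[0, 1] = q.iloc[1, 0] = q_ab
        return rho, q

    @pytest.mark.parametrize("rho,q,kept,sign", [
        (0.85, 0.0005, True, 1),
        (-0.85, 0.0005, True, -1),
        (0.85, 0.002, False, 0),
        (0.75, 0.0005, False, 0),
    ])
    def test_edge_gates(self, rho, q, kept, sign):
        g = build_network(*self._mats(rho, q))
        if kept:
            assert g.has_edge("a", "b")
            assert g.edges["a", "b"]["sign"] == sign
        else:
            assert g.number_of_edges() == 0

    def test_isolated_nodes_excluded(self):
        g = build_network(*self._mats(0.9, 1e-4))
        assert set(g.nodes) == {"a", "b"}

    def test_raising_rho_min_never_adds_edges(self):
        rng = np.random.default_rng(1)
        n = 12
        r = np.corrcoef(rng.normal(size=(n, 30)))
        ids = [f"a{i}" for i in range(n)]
        rho = pd.DataFrame(r, index=ids, columns=ids)
        q = pd.DataFrame(np.full((n, n), 1e-4), index=ids, columns=ids)
        sizes = [build_network(rho, q, rho_min=rm).number_of_edges()
                 for rm in (0.2, 0.5, 0.8, 0.95)]
        assert sizes == sorted(sizes, reverse=True)


class TestMetricsAndModules:
    def test_triangle_metrics(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        m = network_metrics(g)
        assert m.average_degree == pytest.approx(2.0)
        assert m.connectance == pytest.approx(1.0)
        assert m.n_negative == 0

    def test_two_disjoint_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        m = network_metrics(g)
        assert m.average_degree == pytest.approx(1.0)
        assert m.connectance == pytest.approx(1.0 / 3.0)
        assert m.largest_component_fraction == pytest.approx(0.5)

    def test_two_cliques_split(self):
        g1 = nx.complete_graph(range(5))
        g2 = nx.complete_graph(range(5, 10))
        g = nx.union(g1, g2)
        g.add_edge(0, 5)
        modules, q = detect_modules(g, seed=0)
        assert len(set(modules.values())) == 2
        assert len({modules[i] for i in range(5)}) == 1
        assert len({modules[i] for i in range(5, 10)}) == 1
        assert q > 0.3

    def test_single_clique_one_module(self):
        modules, _ = detect_modules(nx.complete_graph(4), seed=0)
        assert len(set(modules.values())) == 1

    def test_deterministic(self):
        g = nx.erdos_renyi_graph(30, 0.2, seed=42)
        assert detect_modules(g, 7) == detect_modules(g, 7)


class TestZiPi:
    def test_pi_analytic_cases(self):
        g1 = nx.complete_graph(range(5))
        g2 = nx.complete_graph(range(5, 10))
        g = nx.union(g1, g2)
        modules = {i: 0 if i < 5 else 1 for i in range(10)}
        # connector with 2 edges into each clique
        g.add_node("x")
        for nb in (0, 1, 5, 6):
            g.add_edge("x", nb)
        modules["x"] = 0
        topo = {t.asv_id: t for t in zi_pi(g, modules)}
        assert topo["x"].pi == pytest.approx(0.5)  # 1 - (0.5^2 + 0.5^2)
        assert topo[9].pi == pytest.approx(0.0)    # all edges within module
        assert max(t.pi for t in topo.values()) == topo["x"].pi

    def test_pi_degree_partition_identity(self):
        rng = np.random.default_rng(2)
        g = nx.erdos_renyi_graph(25, 0.25, seed=3)
        modules, _ = detect_modules(g, 0)
        for t in zi_pi(g, modules):
            per_mod = {}
            for nb in g.neighbors(t.asv_id):
                per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
            assert sum(per_mod.values()) == t.degree
            assert 0 <= t.pi < 1

    def test_roles_respect_thresholds(self):
        g1 = nx.complete_graph(range(5))
        modules = {i: 0 for i in range(5)}
        topo = zi_pi(g1, modules, zi_threshold=2.5, pi_threshold=0.62)
        assert all(t.role == "peripheral" for t in topo)  # symmetric clique
        assert not any(t.keystone for t in topo)

    def test_missing_module_assignment_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValidationError):
            zi_pi(g, {"a": 0})


class TestCompareNetworks:
    def test_set_arithmetic(self):
        def g(nodes):
            gr = nx.Graph()
            gr.add_nodes_from(nodes)
            return gr
        nets = {"S": g({"a", "b", "c"}), "M": g({"b", "c", "d"}),
                "D": g({"c", "e"})}
        out = compare_networks(nets)
        assert out["S&M"] == 2
        assert out["S&D"] == 1
        assert out["M&D"] == 1
        assert out["S&M&D"] == 1

    def test_identical_and_disjoint(self):
        a = nx.complete_graph(3)
        out = compare_networks({"x": a, "y": a.copy()})
        assert out["x&y"] == 3
        b = nx.Graph()
        b.add_nodes_from(["q", "r"])
        assert compare_networks({"x": a, "z": b})["x&z"] == 0


class TestEndToEndGates:
    def test_emitted_edges_resatisfy_gates(self, sim_default):
        from microdepth import build_cooccurrence_network
        table, meta, *_ = sim_default
        net = build_cooccurrence_network(table, meta, "S")
        filtered = filter_for_network(
            table, 5e-3, 0.5,
            [s for s in table.sample_ids if s in set(meta.samples_in_layer("S"))])
        rho, p = spearman_matrix(filtered)
        q = adjusted_p_matrix(p)
        assert net.number_of_edges() > 0
        for a, b, data in net.edges(data=True):
            assert abs(rho.loc[a, b]) >= 0.8
            assert q.loc[a, b] <= 0.001
            assert data["sign"] == (1 if rho.loc[a, b] > 0 else -1)
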