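import math

import networkx as nx
import numpy as np
import pytest

import mibinet as mb
from mibinet.network import CorrelationEstimate, MicrobialNetwork
from helpers import betweenness_oracle, iter_partitions, random_count_table


def _net(edges):
    g = nx.Graph()
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=e[2])
        else:
            g.add_edge(e[0], e[1], weight=1.0)
    return MicrobialNetwork(graph=g)


def _corr_estimate(matrix, taxa):
    return CorrelationEstimate(
        taxon_ids=list(taxa), correlation=np.asarray(matrix, float), n_inner_resamples=0
    )


class TestSparcc:
    def test_contract_on_random_table(self, rng):
        t = random_count_table(rng, n_samples=20, n_taxa=8, depth=2000)
        est = mb.sparcc(t, seed=0)
        c = est.correlation
        np.testing.assert_allclose(np.diag(c), 1.0)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert (np.abs(c) <= 1.0).all()

    def test_exactly_proportional_pair(self):
        rng = np.random.default_rng(1)
        base = rng.integers(500, 5000, size=50)
        others = rng.multinomial(20_000, np.ones(4) / 4, size=50)
        counts = np.column_stack([base, 2 * base, others])
        t = mb.CountTable(
            [f"s{i}" for i in range(50)], ["p1", "p2", "a", "b", "c", "d"], counts
        )
        est = mb.sparcc(t, seed=2)
        assert est.correlation[0, 1] > 0.9

    def test_too_few_taxa(self):
        t = mb.CountTable(["a", "b", "c"], ["x", "y", "z"], np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="4 taxa"):
            mb.sparcc(t)

    def test_too_few_samples(self):
        t = mb.CountTable(["a", "b"], list("wxyz"), np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError, match="3 samples"):
            mb.sparcc(t)

    def test_all_zero_taxon_named(self):
        counts = np.ones((5, 4), dtype=int)
        counts[:, 2] = 0
        t = mb.CountTable([f"s{i}" for i in range(5)], list("wxyz"), counts)
        with pytest.raises(ValueError, match="y"):
            mb.sparcc(t)

    def test_iid_small_mean_correlation(self):
        taxa = [f"T{i:02d}" for i in range(50)]
        t, _ = mb.simulate_counts(100, taxa, np.eye(50), depth_mean=5000, seed=11)
        est = mb.sparcc(t, seed=12)
        off = np.abs(est.correlation[np.triu_indices(50, 1)])
        assert off.mean() < 0.1

    def test_depth_rescaling_stability(self):
        taxa = [f"T{i}" for i in range(10)]
        t, _ = mb.simulate_counts(40, taxa, np.eye(10), depth_mean=3000, seed=3)
        e1 = mb.sparcc(t, seed=7)
        counts = t.counts.copy()
        counts[0] *= 10
        t2 = mb.CountTable(t.sample_ids, t.taxon_ids, counts)
        e2 = mb.sparcc(t2, seed=7)
        diff = np.abs(e1.correlation - e2.correlation)[np.triu_indices(10, 1)]
        assert diff.mean() < 0.05

    def test_deterministic_given_seed(self, rng):
        t = random_count_table(rng, n_samples=12, n_taxa=6, depth=800)
        a = mb.sparcc(t, seed=9)
        b = mb.sparcc(t, seed=9)
        np.testing.assert_array_equal(a.correlation, b.correlation)


class TestPermutationThreshold:
    def test_threshold_is_quantile_of_pooled(self, rng):
        t = random_count_table(rng, n_samples=15, n_taxa=6, depth=500)
        null = mb.permutation_threshold(t, trials=5, seed=0, inner_resamples=3)
        assert null.threshold == pytest.approx(
            float(np.quantile(null.values, 0.95))
        )
        assert null.n_trials == 5
        assert len(null.values) == 5 * (6 * 5 // 2)

    def test_tail_zero_gives_max(self, rng):
        t = random_count_table(rng, n_samples=10, n_taxa=5, depth=400)
        null = mb.permutation_threshold(t, trials=3, tail=0.0, seed=1, inner_resamples=3)
        assert null.threshold == pytest.approx(float(null.values.max()))

    def test_deterministic(self, rng):
        t = random_count_table(rng, n_samples=10, n_taxa=5, depth=400)
        a = mb.permutation_threshold(t, trials=3, seed=5, inner_resamples=3)
        b = mb.permutation_threshold(t, trials=3, seed=5, inner_resamples=3)
        assert a.threshold == b.threshold

    def test_bad_trials(self, rng):
        t = random_count_table(rng)
        with pytest.raises(ValueError):
            mb.permutation_threshold(t, trials=0)


class TestBuildNetwork:
    def test_single_supra_threshold_pair(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.5
        c[2, 3] = c[3, 2] = 0.1
        net = mb.build_network(_corr_estimate(c, list("wxyz")), 0.3)
        assert net.n_nodes == 2 and net.n_edges == 1
        assert set(net.nodes) == {"w", "x"}

    def test_threshold_above_max_warns_empty(self):
        c = np.eye(3)
        with pytest.warns(UserWarning, match="empty"):
            net = mb.build_network(_corr_estimate(c, list("abc")), 0.9)
        assert net.n_nodes == 0

    def test_negative_correlations_never_edges(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = -0.99
        with pytest.warns(UserWarning):
            net = mb.build_network(_corr_estimate(c, list("abc")), 0.1)
        assert net.n_edges == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            mb.build_network(_corr_estimate(np.eye(3), list("abc")), 0.0)

    def test_edge_weights_exceed_threshold(self, rng):
        c = np.eye(6)
        iu = np.triu_indices(6, 1)
        vals = rng.uniform(-1, 1, size=len(iu[0]))
        c[iu] = vals
        c = np.triu(c) + np.triu(c, 1).T
        net = mb.build_network(_corr_estimate(c, [f"t{i}" for i in range(6)]), 0.2)
        assert all(w > 0.2 for _, _, w in net.edge_list())


class TestMapEquation:
    def test_triangle_one_module(self):
        net = _net([(0, 1), (1, 2), (0, 2)])
        L = mb.map_equation(net, {0: 0, 1: 0, 2: 0})
        assert L == pytest.approx(math.log2(3))

    def test_singletons_worse_than_one_module_on_clique(self):
        nodes = range(5)
        net = _net([(i, j) for i in nodes for j in nodes if i < j])
        one = mb.map_equation(net, {v: 0 for v in nodes})
        singles = mb.map_equation(net, {v: v for v in nodes})
        assert singles > one

    def test_two_triangles_bridge(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        one = mb.map_equation(net, {v: 0 for v in range(6)})
        two = mb.map_equation(net, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
        assert two < one

    def test_uncovered_node_rejected(self):
        net = _net([(0, 1), (1, 2)])
        with pytest.raises(ValueError, match="cover"):
            mb.map_equation(net, {0: 0, 1: 0})


class TestDetectCommunities:
    def test_two_disconnected_cliques(self):
        edges = [(i, j) for i in range(4) for j in range(4) if i < j]
        edges += [(i, j) for i in range(4, 8) for j in range(4, 8) if i < j]
        net = _net(edges)
        part = mb.detect_communities(net, seed=0)
        assert part.n_modules == 2
        mods = {frozenset(v for v, m in part.modules.items() if m == k)
                for k in set(part.modules.values())}
        assert mods == {frozenset(range(4)), frozenset(range(4, 8))}
        assert part.modularity == pytest.approx(0.5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(12, 0.35, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        nx.set_edge_attributes(g, 1.0, "weight")
        net = MicrobialNetwork(graph=g)
        a = mb.detect_communities(net, seed=4)
        b = mb.detect_communities(net, seed=4)
        assert a.modules == b.modules and a.codelength == b.codelength

    def test_never_worse_than_one_module(self):
        for s in range(5):
            g = nx.gnp_random_graph(10, 0.3, seed=s)
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() == 0:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            net = MicrobialNetwork(graph=g)
            part = mb.detect_communities(net, trials=3, seed=s)
            one = mb.map_equation(net, {v: 0 for v in g.nodes})
            assert part.codelength <= one + 1e-9

    def test_matches_exhaustive_on_small_graphs(self):
        hits = trials = 0
        for s in range(15):
            g = nx.gnp_random_graph(6, 0.5, seed=100 + s)
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            net = MicrobialNetwork(graph=g)
            best = min(
                mb.map_equation(net, {v: i for i, grp in enumerate(p) for v in grp})
                for p in iter_partitions(list(g.nodes))
            )
            part = mb.detect_communities(net, seed=s)
            trials += 1
            hits += abs(part.codelength - best) < 1e-9
        assert hits >= trials - 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mb.detect_communities(MicrobialNetwork(graph=nx.Graph()))


class TestModularity:
    def test_one_module_zero(self):
        net = _net([(0, 1), (1, 2), (0, 2)])
        assert mb.modularity(net, {0: 0, 1: 0, 2: 0}) == pytest.approx(0.0)

    def test_two_disconnected_triangles(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q = mb.modularity(net, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
        assert q == pytest.approx(0.5)

    def test_range_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for s in range(10):
            g = nx.gnp_random_graph(10, 0.4, seed=s)
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            net = MicrobialNetwork(graph=g)
            part = {v: int(rng.integers(0, 3)) for v in g.nodes}
            assert -0.5 <= mb.modularity(net, part) <= 1.0


class TestConnectance:
    def test_paper_table_values(self):
        # printed node/edge counts from the summary tables
        for n, e, expected in ((55, 343, 0.23), (52, 152, 0.11), (93, 624, 0.15)):
            g = nx.gnm_random_graph(n, e, seed=1)
            net = MicrobialNetwork(graph=g)
            assert round(mb.normalized_connectance(net), 2) == expected

    def test_complete_graph(self):
        net = _net([(i, j) for i in range(5) for j in range(5) if i < j])
        assert mb.normalized_connectance(net) == pytest.approx(1.0)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            mb.normalized_connectance(_net([]))


class TestBetweenness:
    def test_path_graph(self):
        net = _net([("A", "B"), ("B", "C")])
        b = mb.betweenness(net).betweenness
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == 0.0

    def test_star(self):
        net = _net([("c", f"l{i}") for i in range(4)])
        b = mb.betweenness(net).betweenness
        assert b["c"] == pytest.approx(1.0)
        assert all(b[f"l{i}"] == 0.0 for i in range(4))

    def test_small_network_warns_zero(self):
        with pytest.warns(UserWarning):
            b = mb.betweenness(_net([("a", "b")])).betweenness
        assert (b == 0).all()

    def test_matches_enumeration_oracle(self):
        for s in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=s)
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 3:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            mine = mb.betweenness(MicrobialNetwork(graph=g)).betweenness
            oracle = betweenness_oracle(g)
            for v in g.nodes:
                assert mine[v] == pytest.approx(oracle[v], abs=1e-9)


class TestKeystones:
    def test_all_below_cutoff_empty(self):
        net = _net([(i, j) for i in range(4) for j in range(4) if i < j])
        cent = mb.betweenness(net)
        assert mb.keystone_taxa(cent, 0.10) == []

    def test_star_center_sole_keystone(self):
        net = _net([("c", f"l{i}") for i in range(4)])
        cent = mb.betweenness(net)
        assert mb.keystone_taxa(cent, 0.10) == ["c"]

    def test_ordering_and_ties(self):
        import pandas as pd

        from mibinet.network import CentralitySummary

        cent = CentralitySummary(
            betweenness=pd.Series({"b": 0.5, "a": 0.5, "c": 0.9, "d": 0.01})
        )
        assert mb.keystone_taxa(cent, 0.10) == ["c", "a", "b"]

    def test_bad_cutoff(self):
        net = _net([("a", "b"), ("b", "c")])
        with pytest.raises(ValueError):
            mb.keystone_taxa(mb.betweenness(net), 0.0)


class TestNeighborCorrelations:
    def test_sorted_descending_truncated(self):
        net = _net([("f", "a", 0.3), ("f", "b", 0.8), ("f", "c", 0.5), ("a", "b", 0.4)])
        out = mb.neighbor_correlations(net, "f", top_n=2)
        assert out == [("b", 0.8), ("c", 0.5)]

    def test_absent_focal_errors(self):
        net = _net([("a", "b", 0.5)])
        with pytest.raises(KeyError):
            mb.neighbor_correlations(net, "zzz")

    def test_weights_exceed_threshold(self):
        c = np.eye(5)
        c[0, 1] = c[1, 0] = 0.6
        c[0, 2] = c[2, 0] = 0.4
        net = mb.build_network(
            _corr_estimate(c, ["f", "a", "b", "x", "y"]), 0.3
        )
        for _, w in mb.neighbor_correlations(net, "f", 5):
            assert w > 0.3
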