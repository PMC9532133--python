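"""Weighted proximity distance, the randomized null, and the drug screen."""

import math

import networkx as nx
import numpy as np
import pytest

from mirnetprox.proximity import (
    DegenerateNullError,
    NoPathError,
    ProximityRecord,
    null_distribution,
    omega,
    proximity_d,
    proximity_z,
    records_table,
    screen_drugs,
    shortest_distance,
    standardize,
)


def floyd_warshall_oracle(graph):
    """All-pairs hop counts by the cubic dynamic program."""
    nodes = sorted(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in graph.edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return nodes, idx, dist


def proximity_oracle(S, T, graph):
    """Brute-force double loop over T x S on top of the oracle distances."""
    nodes, idx, dist = floyd_warshall_oracle(graph)
    s_set = set(S)
    terms = []
    dropped = 0
    for t in sorted(set(T)):
        if t not in idx:
            dropped += 1
            continue
        best = min(dist[idx[s], idx[t]] for s in S if s in idx)
        if not np.isfinite(best):
            dropped += 1
            continue
        w = 0.0 if t in s_set else -math.log(graph.degree(t) + 1)
        terms.append(best + w)
    return (float(np.mean(terms)) if terms else None), dropped


class TestShortestDistance:
    def test_adjacent_and_self(self):
        g = nx.path_graph(3)
        assert shortest_distance(g, 0, 1) == 1
        assert shortest_distance(g, 1, 1) == 0
        assert shortest_distance(g, 0, 2) == shortest_distance(g, 2, 0) == 2

    def test_missing_node_named(self):
        g = nx.path_graph(3)
        with pytest.raises(KeyError, match="99"):
            shortest_distance(g, 0, 99)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall(self, seed):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        nodes, idx, dist = floyd_warshall_oracle(g)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            u, v = rng.choice(nodes, 2)
            if np.isfinite(dist[idx[u], idx[v]]):
                assert shortest_distance(g, u, v) == dist[idx[u], idx[v]]


class TestOmega:
    def test_member_of_s_is_zero(self):
        g = nx.path_graph(3)
        assert omega(1, {1}, g) == 0.0

    def test_degree_zero_is_zero(self):
        g = nx.Graph()
        g.add_node("lonely")
        assert omega("lonely", set(), g) == 0.0

    def test_degree_two_closed_form(self):
        g = nx.path_graph(3)
        assert omega(1, set(), g) == pytest.approx(-math.log(3))

    @pytest.mark.parametrize("seed", range(3))
    def test_analytic_across_random_graphs(self, seed):
        g = nx.gnp_random_graph(25, 0.2, seed=seed)
        S = set(range(5))
        for v in g.nodes():
            expected = 0.0 if v in S else -math.log(g.degree(v) + 1)
            assert omega(v, S, g) == pytest.approx(expected)


class TestProximityD:
    def test_targets_inside_s_give_zero(self):
        g = nx.path_graph(5)
        d, used, dropped = proximity_d({0, 1, 2}, {1, 2}, g)
        assert d == 0.0 and dropped == 0

    def test_three_node_path_hand_case(self):
        g = nx.path_graph(3)  # a-b-c as 0-1-2, deg(2)=1
        d, _, _ = proximity_d({0}, {2}, g)
        assert d == pytest.approx(2 - math.log(2))
        assert d == pytest.approx(1.3069, abs=1e-4)

    def test_averaging_contract(self):
        g = nx.path_graph(4)
        term = lambda t: shortest_distance(g, 0, t) - math.log(g.degree(t) + 1)
        d, _, _ = proximity_d({0}, {2, 3}, g)
        assert d == pytest.approx((term(2) + term(3)) / 2)

    def test_unreachable_targets_dropped_not_infinite(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("island")
        d, used, dropped = proximity_d({"a"}, {"b", "island", "ghost"}, g)
        assert used == 1 and dropped == 2
        assert np.isfinite(d)

    def test_all_targets_unreachable_errors(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("island")
        with pytest.raises(NoPathError):
            proximity_d({"a"}, {"island"}, g)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(int(rng.integers(10, 50)), 0.12, seed=seed)
        nodes = sorted(g.nodes())
        S = list(rng.choice(nodes, int(rng.integers(2, 6)), replace=False))
        T = list(rng.choice(nodes, int(rng.integers(2, 8)), replace=False))
        expected, exp_dropped = proximity_oracle(S, T, g)
        if expected is None:
            with pytest.raises(NoPathError):
                proximity_d(S, T, g)
        else:
            d, used, dropped = proximity_d(S, T, g)
            assert d == pytest.approx(expected, abs=1e-12)
            assert dropped == exp_dropped

    @pytest.mark.parametrize("seed", range(5))
    def test_enlarging_s_never_increases_distance(self, seed):
        # with omega held fixed (targets outside S and the added gene)
        rng = np.random.default_rng(seed)
        g = nx.connected_watts_strogatz_graph(30, 4, 0.3, seed=seed)
        nodes = sorted(g.nodes())
        S = set(rng.choice(nodes, 4, replace=False))
        pool = [v for v in nodes if v not in S]
        v = pool[0]
        T = set(rng.choice(pool[1:], 5, replace=False)) - {v}
        d1, _, _ = proximity_d(S, T, g)
        d2, _, _ = proximity_d(S | {v}, T, g)
        assert d2 <= d1 + 1e-12

    def test_module_of_size_one_is_single_source(self):
        g = nx.path_graph(6)
        for t in range(1, 6):
            d, _, _ = proximity_d({0}, {t}, g)
            assert d == pytest.approx(t - math.log(g.degree(t) + 1))


class TestNull:
    def test_fixed_seed_reproducible(self):
        g = nx.barabasi_albert_graph(60, 2, seed=0)
        a = null_distribution({0, 1, 2}, 5, g, n_reps=10, seed=99)
        b = null_distribution({0, 1, 2}, 5, g, n_reps=10, seed=99)
        assert np.array_equal(a, b)

    def test_all_nodes_in_s_degenerate(self):
        g = nx.complete_graph(5)
        S = set(g.nodes())
        null = null_distribution(S, 2, g, n_reps=20, seed=0)
        assert np.all(null == 0.0)
        with pytest.raises(DegenerateNullError) as err:
            standardize(0.0, null)
        assert err.value.null_mean == 0.0

    def test_cycle_single_node_null_mean_matches_enumeration(self):
        g = nx.cycle_graph(12)
        S = {0}
        # exhaustive single-node enumeration of d + omega over all nodes
        terms = [
            min(v, 12 - v) + (0.0 if v == 0 else -math.log(3))
            for v in range(12)
        ]
        expected = np.mean(terms)
        null = null_distribution(S, 1, g, n_reps=4000, seed=3)
        se = np.std(terms) / math.sqrt(4000)
        assert abs(null.mean() - expected) < 4 * se

    def test_size_larger_than_graph_errors(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            null_distribution({0}, 10, g, n_reps=5, seed=0)

    def test_degree_binned_mode_deterministic_and_finite(self):
        g = nx.barabasi_albert_graph(80, 2, seed=1)
        degs = [g.degree(v) for v in (0, 1, 5, 40)]
        a = null_distribution({0, 1}, 4, g, n_reps=50, seed=5,
                              mode="degree_binned", match_degrees=degs)
        b = null_distribution({0, 1}, 4, g, n_reps=50, seed=5,
                              mode="degree_binned", match_degrees=degs)
        assert np.array_equal(a, b)
        assert np.isfinite(a).all()

    def test_doubling_reps_converges(self):
        g = nx.barabasi_albert_graph(100, 1, seed=2)
        S = set(range(10))
        small = null_distribution(S, 6, g, n_reps=2000, seed=1)
        big = null_distribution(S, 6, g, n_reps=4000, seed=2)
        tol = 3 * small.std() / math.sqrt(2000)
        assert abs(small.mean() - big.mean()) < tol


class TestZAndScreen:
    def test_three_point_hand_case(self):
        mu, sd, z, p = standardize(1.0, np.array([1.0, 2.0, 3.0]))
        assert (mu, sd) == (2.0, 1.0)
        assert z == pytest.approx(-1.0)
        assert p == pytest.approx(0.5)

    def test_z_zero_at_null_mean(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, z, _ = standardize(2.5, null)
        assert z == pytest.approx(0.0)

    def test_empirical_p_add_one_bound(self):
        null = np.linspace(5, 6, 100)
        _, _, _, p = standardize(0.0, null)
        assert p == pytest.approx(1 / 101)

    def test_proximity_z_record_fields(self):
        g = nx.barabasi_albert_graph(80, 1, seed=3)
        S = set(range(8))
        rec = proximity_z(S, {30, 40, 50}, g, n_reps=200, seed=7, drug_id="d1")
        assert rec.z == pytest.approx((rec.d_obs - rec.null_mean) / rec.null_sd)
        assert 1 / (rec.n_reps + 1) <= rec.p_empirical <= 1.0

    def test_screen_all_p_one_empty(self):
        recs = [ProximityRecord("d1", 1.0, 1.0, 0.5, 0.0, 1.0, 0.5, 100, 3, 0)]
        assert len(screen_drugs(recs, fdr_max=0.05)) == 0

    def test_screen_single_drug_bh_identity(self):
        p = 1 / 101
        recs = [ProximityRecord("d1", 0.0, 2.0, 0.5, -4.0, p, 1e-5, 100, 3, 0)]
        hits = screen_drugs(recs, fdr_max=0.05)
        assert list(hits["drug_id"]) == ["d1"]
        assert hits["fdr"].iloc[0] == pytest.approx(p)

    def test_screen_requires_negative_z(self):
        p = 1 / 1001
        recs = [ProximityRecord("d1", 5.0, 2.0, 0.5, 6.0, p, 1e-9, 1000, 3, 0)]
        assert len(screen_drugs(recs, fdr_max=0.05)) == 0

    def test_records_table_columns(self):
        recs = [ProximityRecord("d1", 0.0, 2.0, 0.5, -4.0, 0.01, 1e-5, 100, 3, 1)]
        tab = records_table(recs)
        assert {"drug_id", "d_obs", "mu", "sigma", "z",
                "p_empirical", "p_parametric"} <= set(tab.columns)

    def test_planted_inside_module_beats_random(self, study):
        recs = {
            r.drug_id: r
            for r in [
                proximity_z(study.truth.disease_module,
                            study.drug_targets[d], study.ppi,
                            n_reps=500, seed=11, drug_id=d)
                for d in sorted(study.drug_targets)
            ]
        }
        planted = recs["DRUG_PLANTED"]
        assert all(planted.z < recs[d].z for d in recs if d != "DRUG_PLANTED")
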