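import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from networkx.algorithms.community import modularity as nx_modularity

from reporternet.exceptions import InsufficientDataError, ValidationError
from reporternet.netstats import (
    barabasi_graph,
    degree_distribution,
    fastgreedy,
    girvan_newman,
    mcode,
    modularity,
    powerlaw_mle,
    powerlaw_regression,
)


class TestDegreeDistribution:
    def test_triangle(self):
        assert degree_distribution(nx.complete_graph(3)) == {2: 1.0}

    def test_star4(self):
        assert degree_distribution(nx.star_graph(3)) == {1: 0.75, 3: 0.25}

    def test_zero_degree_nodes_counted(self):
        g = nx.path_graph(2)
        g.add_node("iso")
        d = degree_distribution(g)
        assert d[0] == pytest.approx(1 / 3)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sums_to_one(self, seed):
        g = nx.gnp_random_graph(30, 0.1, seed=seed)
        assert sum(degree_distribution(g).values()) == pytest.approx(1.0, abs=1e-12)


class TestPowerlawRegression:
    def test_exact_log_linear(self):
        ks = [1, 2, 3, 4]
        raw = {k: k**-2.0 for k in ks}
        z = sum(raw.values())
        gamma, r2 = powerlaw_regression({k: v / z for k, v in raw.items()})
        assert gamma == pytest.approx(2.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_distribution_gamma_zero(self):
        gamma, r2 = powerlaw_regression({1: 0.25, 2: 0.25, 4: 0.25, 8: 0.25})
        assert gamma == pytest.approx(0.0, abs=1e-12)

    def test_single_degree_insufficient(self):
        with pytest.raises(InsufficientDataError):
            powerlaw_regression({3: 1.0})


class TestPowerlawMle:
    def test_continuous_pareto_recovery(self):
        rng = np.random.default_rng(42)
        x = (1.0 - rng.random(10_000)) ** (-1.0 / 1.5)  # gamma = 2.5, x_min = 1
        fit = powerlaw_mle(x, x_min=1, n_bootstrap=0)
        assert not fit.discrete
        assert fit.gamma_mle == pytest.approx(2.5, abs=0.05)
        assert fit.log_likelihood < 0 or fit.log_likelihood > 0  # finite

    def test_ks_p_calibrated_on_true_power_law(self):
        # data genuinely drawn from the fitted law: bootstrap p rarely small
        rng = np.random.default_rng(7)
        ok = 0
        for i in range(50):
            x = (1.0 - rng.random(200)) ** (-1.0 / 1.5)
            fit = powerlaw_mle(x, x_min=1, n_bootstrap=100, seed=1000 + i)
            if fit.ks_p > 0.05:
                ok += 1
        assert ok >= 45

    def test_all_equal_divergent(self):
        with pytest.raises(ValidationError):
            powerlaw_mle([3] * 50, x_min=3)

    def test_ks_p_label_reports_bound_not_zero(self):
        rng = np.random.default_rng(8)
        # exponential tail is a terrible power law: bootstrap never reaches its KS
        x = rng.exponential(0.3, size=2000) + 1.0
        fit = powerlaw_mle(x, x_min=1, n_bootstrap=50, seed=9)
        if fit.ks_p == 0:
            assert fit.ks_p_label == "<0.02"

    def test_regression_agrees_with_mle_on_large_pareto_sample(self):
        rng = np.random.default_rng(10)
        x = (1.0 - rng.random(100_000)) ** (-1.0 / 1.5)  # continuous, gamma = 2.5
        fit = powerlaw_mle(x, x_min=1, n_bootstrap=0)
        # regression needs a binned P(k); keep only well-estimated bins,
        # since single-count tail bins dominate an unweighted OLS
        k = np.floor(x).astype(int)
        vals, counts = np.unique(k[k >= 1], return_counts=True)
        dist = {int(v): c / k.size for v, c in zip(vals, counts) if c >= 5}
        gamma_reg, r2 = powerlaw_regression(dist)
        assert abs(fit.gamma_mle - gamma_reg) < 0.2
        assert r2 > 0.95


class TestBarabasi:
    def test_tree_when_m_is_one(self):
        g = barabasi_graph(50, 1, seed=0)
        assert g.number_of_nodes() == 50
        assert g.number_of_edges() == 49
        assert nx.is_connected(g) and nx.is_forest(g)

    def test_deterministic(self):
        a = barabasi_graph(100, 2, seed=5)
        b = barabasi_graph(100, 2, seed=5)
        assert set(a.edges()) == set(b.edges())

    def test_invalid_m(self):
        with pytest.raises(ValidationError):
            barabasi_graph(5, 5, seed=0)
        with pytest.raises(ValidationError):
            barabasi_graph(5, 0, seed=0)


class TestCommunities:
    def test_fastgreedy_two_cliques(self, two_cliques_bridged):
        res = fastgreedy(two_cliques_bridged)
        assert res.n_communities == 2
        assert res.q == pytest.approx(0.452381, abs=1e-4)
        comms = {frozenset(v for v, c in res.communities.items() if c == lab) for lab in set(res.communities.values())}
        assert comms == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_girvan_newman_two_cliques(self, two_cliques_bridged):
        res = girvan_newman(two_cliques_bridged)
        assert res.n_communities == 2
        assert res.q == pytest.approx(0.452381, abs=1e-4)
        # the bridge is the first removed edge (highest betweenness = 25 cross pairs)
        assert res.dendrogram[0] == ("0", "5")

    def test_q_matches_independent_oracle(self, two_cliques_bridged):
        for algo in (fastgreedy, girvan_newman):
            res = algo(two_cliques_bridged)
            parts = [
                {v for v, c in res.communities.items() if c == lab}
                for lab in set(res.communities.values())
            ]
            assert res.q == pytest.approx(nx_modularity(two_cliques_bridged, parts), abs=1e-9)

    def test_single_clique_trivial_partition(self):
        res = fastgreedy(nx.complete_graph(6))
        assert res.n_communities == 1
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_label_invariance(self, two_cliques_bridged):
        relabel = {i: f"node_{i}" for i in range(10)}
        g2 = nx.relabel_nodes(two_cliques_bridged, relabel)
        assert fastgreedy(g2).q == pytest.approx(fastgreedy(two_cliques_bridged).q, abs=1e-12)

    def test_girvan_newman_deterministic_under_ties(self):
        g = nx.path_graph(3)  # both edges tie on betweenness
        r1 = girvan_newman(g)
        r2 = girvan_newman(g)
        assert r1.communities == r2.communities
        assert r1.dendrogram == r2.dendrogram

    def test_edgeless_rejected(self):
        with pytest.raises(ValidationError):
            fastgreedy(nx.empty_graph(3))
        with pytest.raises(ValidationError):
            girvan_newman(nx.empty_graph(3))

    def test_planted_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        sizes = [20, 20]
        truth = [0] * 20 + [1] * 20
        for seed in range(10):
            g = nx.stochastic_block_model(sizes, [[0.5, 0.02], [0.02, 0.5]], seed=seed)
            for algo in (fastgreedy, girvan_newman):
                res = algo(g)
                pred = [res.communities[v] for v in range(40)]
                assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)


class TestModularityFormula:
    def test_two_clique_hand_value(self, two_cliques_bridged):
        part = {v: 0 if v < 5 else 1 for v in range(10)}
        # 2 x (10/21 - (21/42)^2)
        assert modularity(two_cliques_bridged, part) == pytest.approx(2 * (10 / 21 - 0.25), abs=1e-12)

    def test_edgeless_undefined(self):
        with pytest.raises(ValidationError):
            modularity(nx.empty_graph(2), {0: 0, 1: 0})


class TestMcode:
    def test_k5_with_pendant_haircut(self):
        g = nx.complete_graph(5)
        g.add_edge(0, "pend")
        clusters = mcode(g)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(range(5))

    def test_edgeless_empty(self):
        assert mcode(nx.empty_graph(4)) == []

    def test_direct_bridge_merges_equal_weight_cliques(self):
        # both K4s carry identical vertex weights, so expansion crosses the bridge
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        clusters = mcode(g)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(range(8))

    def test_low_weight_linker_separates_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_node(8)
        g.add_edge(0, 8)
        g.add_edge(8, 4)
        clusters = mcode(g)
        member_sets = {c.members for c in clusters}
        assert member_sets == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_members_induce_connected_subgraph(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        for c in mcode(g):
            assert nx.is_connected(g.subgraph(c.members))

    def test_score_is_density_times_size(self):
        g = nx.complete_graph(6)
        (c,) = mcode(g)
        assert c.score == pytest.approx(6.0)
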