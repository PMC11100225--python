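import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizolink.netcore import (
    CorrelationMatrix,
    CooccurrenceNetwork,
    build_network,
    centralities,
    core_candidates,
    network_stats,
    rank_core_taxa,
    sparcc_matrix,
    spearman_matrix,
)
from rhizolink.tables_io import TaxonAbundanceTable

from conftest import make_table
from graph_oracle import oracle_metrics


def net_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, r=1.0, p=0.0)
    return CooccurrenceNetwork(graph=g, r_min=0.6, p_max=0.05)


def corr_from(r, p, ids=None):
    r = np.asarray(r, dtype=float)
    ids = ids or [f"t{i}" for i in range(r.shape[0])]
    return CorrelationMatrix(ids, r, np.asarray(p, dtype=float), method="spearman")


class TestCoreCandidates:
    def make_prevalence_table(self, n_present, n_samples, level):
        row = np.zeros(n_samples)
        row[:n_present] = level
        filler = np.full(n_samples, 1.0)
        vals = np.vstack([row, filler - row])
        return make_table(vals, kind="relative", taxa=["cand", "rest"])

    def test_prevalent_abundant_taxon_kept(self):
        t = self.make_prevalence_table(38, 40, 2e-4 * 40 / 38)
        assert "cand" in core_candidates(t)

    def test_below_prevalence_dropped(self):
        t = self.make_prevalence_table(29, 40, 0.5)  # 72.5% prevalence
        assert "cand" not in core_candidates(t)

    def test_abundance_threshold_is_strict(self):
        t = self.make_prevalence_table(40, 40, 1e-4)  # mean exactly 1e-4
        assert "cand" not in core_candidates(t)
        t2 = self.make_prevalence_table(40, 40, 1.01e-4)
        assert "cand" in core_candidates(t2)

    def test_empty_result_warns(self):
        t = make_table([[1e-6, 1e-6], [1 - 1e-6, 1 - 1e-6]], kind="relative")
        with pytest.warns(RuntimeWarning, match="no taxa"):
            out = core_candidates(t, prevalence_min=1.0, abundance_min=1.0)
        assert out == []


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(0.1, 3, 12)
        t = make_table(np.vstack([x, np.exp(x), x.max() - x + 0.1]))
        c = spearman_matrix(t)
        assert c.r[0, 1] == pytest.approx(1.0)
        assert c.r[0, 2] == pytest.approx(-1.0)
        assert c.p[0, 1] == 0.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.random((6, 30)))
        c = spearman_matrix(t)
        for i, j in itertools.combinations(range(6), 2):
            ref_r, ref_p = stats.spearmanr(t.values[i], t.values[j])
            assert c.r[i, j] == pytest.approx(ref_r, abs=1e-12)
            assert c.p[i, j] == pytest.approx(ref_p, rel=1e-6)

    def test_null_correlations_are_small(self):
        """Independent vectors at n=1000: |r| < 0.1 in >=95% of 100 replicates."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            t = make_table(rng.random((2, 1000)))
            c = spearman_matrix(t)
            hits += abs(c.r[0, 1]) < 0.1
        assert hits >= 95

    def test_constant_vector_flagged(self):
        t = make_table([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2]])
        c = spearman_matrix(t)
        assert c.flagged == ["t1"]
        assert c.r[0, 1] == 0.0
        assert c.p[0, 1] == 1.0


class TestSparcc:
    @staticmethod
    def basis_counts(seed, n=200, d=50, rho=0.8, depth=50_000):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, d))
        z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        basis = np.exp(z)
        frac = basis / basis.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(depth, p) for p in frac]).T
        df = pd.DataFrame(
            counts, index=[f"t{i}" for i in range(d)], columns=[f"s{j}" for j in range(n)]
        )
        return TaxonAbundanceTable(df, kind="counts")

    def test_seeded_determinism(self):
        t = self.basis_counts(3, n=40, d=30)
        a = sparcc_matrix(t, n_dirichlet=5, n_perm=0, seed=9)
        b = sparcc_matrix(t, n_dirichlet=5, n_perm=0, seed=9)
        np.testing.assert_array_equal(a.r, b.r)

    def test_planted_basis_correlation_recovered(self):
        errs = [
            abs(sparcc_matrix(self.basis_counts(s), n_perm=0, seed=s).r[0, 1] - 0.8)
            for s in range(3)
        ]
        assert max(errs) < 0.15

    def test_null_correlations_bounded(self):
        t = self.basis_counts(11, rho=0.0)
        c = sparcc_matrix(t, n_perm=0, seed=0)
        off = np.abs(c.r[np.triu_indices(50, 1)])
        assert np.percentile(off, 95) < 0.3

    def test_permutation_p_separates_signal_from_noise(self):
        t = self.basis_counts(5, n=60, d=30)
        c = sparcc_matrix(t, n_dirichlet=5, n_perm=49, seed=0)
        assert c.p[0, 1] <= 0.05
        assert c.p[np.triu_indices(30, 1)].min() >= 1 / 50

    def test_too_few_taxa_rejected(self):
        t = self.basis_counts(0, n=40, d=10)
        with pytest.raises(ValueError, match="25 taxa"):
            sparcc_matrix(t)

    def test_relative_table_rejected(self):
        t = make_table(np.full((30, 10), 1 / 30), kind="relative")
        with pytest.raises(ValueError, match="counts"):
            sparcc_matrix(t)


class TestBuildNetwork:
    def test_single_qualifying_pair(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.7
        p = np.full((3, 3), 0.01)
        net = build_network(corr_from(r, p))
        assert net.n_edges == 1
        assert set(net.graph.nodes) == {"t0", "t1"}

    def test_insignificant_p_blocks_edge(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.7
        net = build_network(corr_from(r, np.full((2, 2), 0.2)))
        assert net.n_edges == 0

    def test_complete_graph_edge_count(self):
        q = 5
        net = build_network(corr_from(np.ones((q, q)), np.zeros((q, q))))
        assert net.n_edges == q * (q - 1) // 2


class TestNetworkStats:
    def test_average_degree_identity_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnm_random_graph(12, int(rng.integers(5, 30)), seed=int(rng.integers(1e6)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() == 0:
                continue
            s = network_stats(g)
            assert s.average_degree == pytest.approx(2 * s.n_edges / s.n_nodes)

    def test_triangle(self):
        s = network_stats(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert s.average_degree == pytest.approx(2.0)
        assert s.clustering_coefficient == pytest.approx(1.0)
        assert s.average_path_length == pytest.approx(1.0)

    def test_path_graph_three_nodes(self):
        s = network_stats(net_from_edges([("a", "b"), ("b", "c")]))
        assert s.average_degree == pytest.approx(4 / 3)
        assert s.clustering_coefficient == pytest.approx(0.0)
        assert s.average_path_length == pytest.approx(4 / 3)

    def test_printed_genus_network_consistency(self):
        g = nx.gnm_random_graph(83, 448, seed=1)
        s = network_stats(g)
        assert round(s.average_degree, 1) == 10.8

    def test_modularity_invariant_to_relabeling(self):
        g = nx.gnm_random_graph(15, 30, seed=2)
        s1 = network_stats(g)
        mapping = {v: f"x{v}" for v in g.nodes}  # preserves string-sort order
        s2 = network_stats(nx.relabel_nodes(g, mapping))
        assert s1.modularity == pytest.approx(s2.modularity, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            network_stats(nx.Graph())


class TestCentralities:
    def test_star_center(self):
        c = centralities(net_from_edges([("c", f"l{i}") for i in range(4)]))
        assert c.loc["c", "degree"] == 4
        assert c.loc["c", "closeness"] == pytest.approx(1.0)
        assert c.loc["c", "betweenness"] == pytest.approx(1.0)

    def test_two_disjoint_edges_component_scaled_closeness(self):
        c = centralities(net_from_edges([("a", "b"), ("c", "d")]))
        # Wasserman-Faust: (1/1) * (1/3) within a 2-node component of a 4-node graph
        assert np.allclose(c["closeness"], 1 / 3)

    def test_path_graph_interior_betweenness_matches_oracle(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d")]
        c = centralities(net_from_edges(edges))
        ref = oracle_metrics(["a", "b", "c", "d"], edges)
        for v in "abcd":
            assert c.loc[v, "betweenness"] == pytest.approx(ref["betweenness"][v])

    def test_matches_bfs_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1e6)))
            nodes = [f"n{v}" for v in g.nodes]
            edges = [(f"n{a}", f"n{b}") for a, b in g.edges]
            net = net_from_edges(edges, nodes=nodes)
            cent = centralities(net)
            ref = oracle_metrics(nodes, edges)
            stats_ = network_stats(net)
            assert stats_.average_path_length == pytest.approx(ref["apl"])
            for v in nodes:
                assert cent.loc[v, "betweenness"] == pytest.approx(ref["betweenness"][v])
                assert cent.loc[v, "closeness"] == pytest.approx(ref["closeness"][v])


class TestRankCoreTaxa:
    def test_star_center_selected(self):
        rk = rank_core_taxa(net_from_edges([("c", f"l{i}") for i in range(4)]), k=1)
        assert rk.selected == ["c"]

    def test_full_tie_broken_lexicographically(self):
        rk = rank_core_taxa(net_from_edges([("b", "a")]), k=1)
        assert rk.selected == ["a"]

    def test_fewer_nodes_than_k_warns(self):
        with pytest.warns(RuntimeWarning, match="returning all"):
            rk = rank_core_taxa(net_from_edges([("a", "b")]), k=5)
        assert len(rk.selected) == 2
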