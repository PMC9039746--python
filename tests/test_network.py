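"""Edge inference, topology metrics, and the Erdős–Rényi null ensemble."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salinet import network
from salinet.datatypes import SalinetError
from tests.conftest import make_table, make_taxonomy


class TestPrevalenceFilter:
    def test_boundary_is_inclusive(self):
        # 1 of 4 samples at threshold 0.25 -> kept ("at least 25%")
        table = make_table([[1, 0], [0, 0], [0, 0], [0, 0]], otu_ids=["a", "b"])
        out = network.prevalence_filter(table, 0.25)
        assert out.otu_ids == ["a"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        counts = (rng.random((10, 30)) < 0.3) * rng.integers(1, 9, (10, 30))
        table = make_table(counts)
        out = network.prevalence_filter(table, 0.25)
        expected = [
            o for o in table.otu_ids
            if (table.counts[o] > 0).sum() / 10 >= 0.25
        ]
        assert out.otu_ids == expected

    def test_empty_result_advises(self):
        table = make_table([[0, 0], [0, 0], [0, 0], [1, 0]])
        with pytest.raises(SalinetError, match="lower"):
            network.prevalence_filter(table, 0.9)


class TestSpearmanEdges:
    def test_monotone_and_antimonotone_pairs(self):
        counts = np.array(
            [[1, 2, 9], [2, 4, 7], [3, 8, 5], [4, 16, 3], [5, 30, 1]]
        )
        table = make_table(counts, otu_ids=["up", "up2", "down"])
        edges = network.spearman_edges(table, rho_min=0.6, q_max=0.5)
        recs = {(r.source, r.target): r for r in edges.itertuples()}
        assert recs[("up", "up2")].rho == pytest.approx(1.0)
        assert recs[("up", "down")].rho == pytest.approx(-1.0)
        assert recs[("up", "down")].sign == "negative"

    def test_matches_independent_rank_implementation(self):
        """Hand-rolled average-rank correlation vs the packaged matrix."""
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 40, size=(12, 10))
        counts[:, 0] += 1
        table = make_table(counts)
        rho, _ = network._spearman_matrix(counts.astype(float))

        def rank_avg(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        for a in range(5):
            for b in range(a + 1, 5):
                ra, rb = rank_avg(counts[:, a]), rank_avg(counts[:, b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert rho[a, b] == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 40, size=(10, 12))
        counts += 1
        table = make_table(counts)
        edges = network.spearman_edges(table, rho_min=0.0, q_max=1.1)
        s = edges.sort_values("p")
        assert (s["q"].diff().dropna() >= -1e-12).all()
        assert (s["q"] >= s["p"] - 1e-12).all()

    def test_constant_otu_excluded_with_warning(self):
        counts = np.array([[1, 5, 3], [2, 5, 1], [3, 5, 4], [4, 5, 2]])
        table = make_table(counts, otu_ids=["a", "const", "b"])
        with pytest.warns(UserWarning, match="const"):
            edges = network.spearman_edges(table, rho_min=0.0, q_max=1.1)
        assert "const" not in set(edges["source"]) | set(edges["target"])


class TestBuildNetwork:
    def test_empty_and_dedup(self):
        empty = network.build_network(
            pd.DataFrame(columns=["source", "target", "rho", "sign"])
        )
        assert empty.number_of_nodes() == 0
        dup = pd.DataFrame(
            {
                "source": ["a", "a"],
                "target": ["b", "b"],
                "rho": [0.9, 0.9],
                "sign": ["positive", "positive"],
            }
        )
        g = network.build_network(dup)
        assert g.number_of_edges() == 1


class TestTopology:
    def test_closed_forms_from_printed_counts(self):
        """Any graph with the given N and L has avgK = 2L/N and
        connectance = 2L/(N(N-1)) (the closed-form metrics of the three
        published salinity-class networks)."""
        for n, l, avgk, conn in [
            (92, 300, 6.52173913, 0.071667463),
            (120, 554, 9.233333333, 0.077591036),
            (308, 3685, 23.92857143, 0.077943229),
        ]:
            assert network.average_degree(n, l) == pytest.approx(avgk, abs=5e-9)
            assert network.connectance(n, l) == pytest.approx(conn, abs=5e-10)
            g = nx.gnm_random_graph(n, l, seed=1)
            topo = network.topology(g)
            assert topo.avg_degree == pytest.approx(avgk, abs=5e-9)
            assert topo.connectance == pytest.approx(conn, abs=5e-10)

    def test_complete_triangle(self):
        g = nx.complete_graph(3)
        for u, v in g.edges:
            g[u][v]["sign"] = "positive"
        topo = network.topology(g)
        assert topo.avg_clustering == 1.0
        assert topo.avg_path_distance == 1.0
        assert topo.diameter == 1
        assert topo.connectance == 1.0
        assert topo.n_positive == 3

    def test_matches_igraph_on_random_graph(self):
        import igraph as ig

        g = nx.gnm_random_graph(20, 40, seed=5)
        for u, v in g.edges:
            g[u][v]["sign"] = "positive"
        topo = network.topology(g)
        h = ig.Graph.from_networkx(g)
        assert topo.avg_clustering == pytest.approx(
            h.transitivity_avglocal_undirected(mode="zero"), abs=1e-9
        )
        assert topo.avg_path_distance == pytest.approx(
            h.average_path_length(directed=False), abs=1e-9
        )
        assert topo.diameter == h.diameter()
        # same partition scored by igraph's modularity formula
        q, communities = network.modularity_greedy(g)
        membership = {}
        for ci, comm in enumerate(communities):
            for node in comm:
                membership[node] = ci
        assert q == pytest.approx(
            h.modularity([membership[v["_nx_name"]] for v in h.vs]), abs=1e-9
        )

    def test_power_law_r2_perfect_line(self):
        # degree frequencies on an exact log-log line -> R^2 = 1
        degrees = [1] * 27 + [3] * 9 + [9] * 3 + [27] * 1
        assert network._power_law_r2(degrees) == pytest.approx(1.0, abs=1e-12)


class TestErNullEnsemble:
    def test_forced_triangle_has_zero_sd(self):
        out = network.er_null_ensemble(3, 3, n_graphs=20, seed=0)
        assert out.means["avg_clustering"] == 1.0
        assert out.sds["avg_clustering"] == 0.0

    def test_mean_clustering_near_edge_density(self):
        n, l, reps = 30, 100, 200
        out = network.er_null_ensemble(
            n, l, n_graphs=reps, seed=1, metrics=("avg_clustering",)
        )
        density = 2 * l / (n * (n - 1))
        se = out.sds["avg_clustering"] / np.sqrt(reps)
        assert abs(out.means["avg_clustering"] - density) < 3 * se

    def test_seeded_reproducibility_and_infeasible_l(self):
        a = network.er_null_ensemble(10, 20, n_graphs=30, seed=3)
        b = network.er_null_ensemble(10, 20, n_graphs=30, seed=3)
        assert a.means == b.means and a.sds == b.sds
        with pytest.raises(SalinetError):
            network.er_null_ensemble(4, 10)

    def test_modular_graph_exceeds_null_modularity(self):
        """Two dense cliques joined by one edge: observed Q is far above
        the ER ensemble mean."""
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g.add_edge(0, 8)
        topo_q, _ = network.modularity_greedy(g)
        out = network.er_null_ensemble(
            g.number_of_nodes(), g.number_of_edges(), n_graphs=100, seed=2,
            metrics=("modularity",),
        )
        assert topo_q > out.means["modularity"] + 3 * out.sds["modularity"]


class TestDegreeProportion:
    def test_enumeration_and_normalisation(self):
        edges = pd.DataFrame(
            {
                "source": ["a", "a", "b"],
                "target": ["b", "c", "c"],
                "rho": [0.9, 0.8, 0.7],
                "sign": ["positive"] * 3,
            }
        )
        taxonomy = make_taxonomy(
            ["a", "b", "c"],
            lineages={
                "a": "E;P;C;O1;F;G",
                "b": "E;P;C;O1;F;G",
                "c": "E;P;C;O2;F;G",
            },
        )
        g = network.build_network(edges, taxonomy)
        frac = network.degree_proportion_by_taxon(g, taxonomy)
        assert frac.sum() == pytest.approx(1.0)
        assert frac["O1"] == pytest.approx(4 / 6)
        assert frac["O2"] == pytest.approx(2 / 6)


class TestEnvOtuNetwork:
    def test_planted_correlated_variable_degree(self):
        """A variable equal to one OTU's profile and monotone with a block
        of OTUs: its degree counts exactly those associations."""
        rng = np.random.default_rng(9)
        n = 16
        driver = np.sort(rng.random(n)) * 10
        counts = np.zeros((n, 12), dtype=int)
        for j in range(10):  # 10 OTUs monotone in the driver
            counts[:, j] = (driver * (j + 1) * 3).astype(int) + 1
        counts[:, 10] = rng.integers(1, 50, n)
        counts[:, 11] = rng.integers(1, 50, n)
        table = make_table(counts)
        variables = pd.DataFrame(
            {"driver": driver, "noise": rng.normal(size=n)}, index=table.sample_ids
        )
        g, env_degree = network.env_otu_network(table, variables)
        assert env_degree["driver"] == 10
        assert g.nodes["driver"]["type"] == "environment"

    def test_shuffled_variable_rarely_connects(self):
        rng = np.random.default_rng(10)
        clean = 0
        runs = 20
        for r in range(runs):
            counts = rng.integers(1, 60, size=(24, 10))
            table = make_table(counts)
            variables = pd.DataFrame(
                {"shuffled": rng.permutation(np.arange(24.0))}, index=table.sample_ids
            )
            _, env_degree = network.env_otu_network(table, variables)
            clean += env_degree["shuffled"] == 0
        assert clean >= 0.95 * runs - 1
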