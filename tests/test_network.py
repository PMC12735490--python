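"""Co-occurrence networks: correlation matrices, thresholds, hubs, export."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fibersynergy import network
from fibersynergy.network import (
    NetworkConfig, NetworkError, build_network, centrality_and_hubs,
    export_network, import_network, taxa_correlation_matrix,
)


def _factor_counts(rng, n_samples=60, coupled=6, background=20, loading=0.9):
    """Abundances where `coupled` taxa share one latent factor.

    The background community is abundant (log-scale location +2) so the
    coupled module is a minor fraction of each sample and closure to
    relative abundances does not strip out the shared factor.
    """
    z = rng.normal(size=n_samples)
    cols = {}
    for i in range(coupled):
        latent = loading * z + np.sqrt(1 - loading**2) * rng.normal(size=n_samples)
        cols[f"mod_{i}"] = np.exp(latent)
    for i in range(background):
        cols[f"bg_{i}"] = np.exp(2.0 + rng.normal(size=n_samples))
    df = pd.DataFrame(cols).T
    df.columns = [f"s{j}" for j in range(n_samples)]
    return df


class TestCorrelationMatrix:
    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(401)
        counts = _factor_counts(rng)
        rho, p = taxa_correlation_matrix(counts)
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(np.diag(p), 0.0)

    def test_min_samples_enforced(self):
        counts = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(NetworkError, match=">= 5 samples"):
            taxa_correlation_matrix(counts)

    def test_shared_latent_factor_detected(self):
        rng = np.random.default_rng(403)
        counts = _factor_counts(rng, coupled=2, background=8, loading=0.95)
        rho, _ = taxa_correlation_matrix(counts)
        assert rho.loc["mod_0", "mod_1"] > 0.8

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(405)
        counts = _factor_counts(rng)
        shuffled = counts[list(rng.permutation(counts.columns))]
        rho_a, _ = taxa_correlation_matrix(counts)
        rho_b, _ = taxa_correlation_matrix(shuffled)
        pd.testing.assert_frame_equal(rho_a, rho_b)


class TestBuildNetwork:
    def _matrices(self, rho_values, n=30, n_taxa=4):
        taxa = [f"t{i}" for i in range(n_taxa)]
        rho = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
        p = pd.DataFrame(np.ones_like(rho), index=taxa, columns=taxa)
        for (i, j), r in rho_values.items():
            rho.iloc[i, j] = rho.iloc[j, i] = r
            # asymptotic t-approximation for the edge's p
            t = abs(r) * np.sqrt((n - 2) / (1 - r**2))
            from scipy import stats as sps
            pv = 2 * sps.t.sf(t, n - 2)
            p.iloc[i, j] = p.iloc[j, i] = pv
        np.fill_diagonal(p.values, 0.0)
        return rho, p

    def test_zero_correlations_give_empty_network(self):
        rho, p = self._matrices({})
        g = build_network(rho, p)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 0

    def test_unreachable_rho_min_empties_any_network(self):
        rho, p = self._matrices({(0, 1): 0.95, (1, 2): -0.9})
        g = build_network(rho, p, NetworkConfig(rho_min=1.01))
        assert g.number_of_edges() == 0

    def test_planted_module_fully_recovered(self):
        rng = np.random.default_rng(407)
        counts = _factor_counts(rng, n_samples=100, coupled=6, background=10, loading=0.92)
        rho, p = taxa_correlation_matrix(counts)
        g = build_network(rho, p)
        module = [f"mod_{i}" for i in range(6)]
        within = [(a, b) for i, a in enumerate(module) for b in module[i + 1:]]
        assert all(g.has_edge(a, b) for a, b in within)
        assert all(g.edges[a, b]["sign"] == "positive" for a, b in within)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(409)
        counts = _factor_counts(rng, coupled=5, background=10, loading=0.85)
        rho, p = taxa_correlation_matrix(counts)
        loose = set(build_network(rho, p, NetworkConfig(alpha=0.1, rho_min=0.5)).edges)
        tight_rho = set(build_network(rho, p, NetworkConfig(alpha=0.1, rho_min=0.7)).edges)
        tight_alpha = set(build_network(rho, p, NetworkConfig(alpha=0.01, rho_min=0.5)).edges)
        assert tight_rho <= loose
        assert tight_alpha <= loose

    def test_degrees_sum_to_twice_edges(self):
        rng = np.random.default_rng(411)
        counts = _factor_counts(rng, coupled=5, background=8, loading=0.9)
        rho, p = taxa_correlation_matrix(counts)
        g = build_network(rho, p)
        assert sum(dict(g.degree).values()) == 2 * g.number_of_edges()


class TestHubs:
    def _star(self):
        g = nx.Graph()
        for i in range(5):
            g.add_edge("hub", f"leaf{i}", rho=0.9, q=0.001, sign="positive")
        return g

    def test_star_graph_ranking(self):
        hubs = centrality_and_hubs(self._star(), k=1)
        assert hubs["taxon"].iloc[0] == "hub"
        assert hubs["degree"].iloc[0] == 5

    def test_tie_break_is_deterministic(self):
        g = nx.Graph()
        for tri, rho in (("abc", 0.9), ("xyz", 0.7)):
            for a, b in zip(tri, tri[1:] + tri[0]):
                g.add_edge(a, b, rho=rho, q=0.01, sign="positive")
        hubs = centrality_and_hubs(g, k=6)
        # all degree 2; stronger triangle first by summed |rho|, then lexicographic
        assert list(hubs["taxon"]) == ["a", "b", "c", "x", "y", "z"]

    def test_empty_network_empty_ranking(self):
        assert len(centrality_and_hubs(nx.Graph(), k=3)) == 0

    def test_betweenness_option(self):
        hubs = centrality_and_hubs(self._star(), k=1, centrality="betweenness")
        assert hubs["taxon"].iloc[0] == "hub"


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        g = TestHubs()._star()
        for node in g.nodes:
            g.nodes[node]["degree"] = g.degree(node)
        path = tmp_path / "net.graphml"
        export_network(g, path, "graphml")
        back = import_network(path, "graphml")
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for u, v, d in back.edges(data=True):
            assert d["rho"] == pytest.approx(g.edges[u, v]["rho"])
            assert d["sign"] == g.edges[u, v]["sign"]

    def test_edge_tsv_round_trip(self, tmp_path):
        g = TestHubs()._star()
        path = tmp_path / "net.tsv"
        export_network(g, path, "edge_tsv")
        back = import_network(path, "edge_tsv")
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))

    def test_empty_network_exports_valid_files(self, tmp_path):
        g = nx.Graph()
        export_network(g, tmp_path / "empty.graphml", "graphml")
        export_network(g, tmp_path / "empty.tsv", "edge_tsv")
        assert import_network(tmp_path / "empty.graphml").number_of_edges() == 0
        assert import_network(tmp_path / "empty.tsv", "edge_tsv").number_of_edges() == 0

    def test_sign_attribute_consistent(self):
        rng = np.random.default_rng(413)
        counts = _factor_counts(rng, coupled=4, background=6, loading=0.9)
        rho, p = taxa_correlation_matrix(counts)
        g = build_network(rho, p, NetworkConfig(rho_min=0.3, alpha=0.2))
        for u, v, d in g.edges(data=True):
            assert d["sign"] == ("positive" if d["rho"] >= 0 else "negative")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(NetworkError, match="unknown export format"):
            export_network(nx.Graph(), tmp_path / "x", "dot")
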