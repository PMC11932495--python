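from itertools import combinations
from math import factorial

import networkx as nx
import numpy as np
import pytest

from comarker.expression import ConfigurationError
from comarker.network import (
    compute_centralities,
    consensus_hubs,
    epc_centrality,
    mcc_centrality,
    mcode_clusters,
    mnc_dmnc,
    radiality_centrality,
    sorensen_distance,
    sorensen_similarity,
    stress_centrality,
)
from comarker.synth import generate_ppi_graph


# --- independent oracles ---------------------------------------------------

def brute_force_betweenness_stress(g):
    """Enumerate every shortest path explicitly (small graphs only)."""
    nodes = list(g.nodes)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            count = sum(v in p for p in sps)
            stress[v] += count
            bet[v] += count / len(sps)
    return bet, stress


def brute_force_mcc(g):
    """All maximal cliques by exhaustive subset enumeration."""
    nodes = list(g.nodes)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for comb in combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in combinations(comb, 2)):
                cliques.append(frozenset(comb))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    mcc = {v: 0.0 for v in nodes}
    for c in maximal:
        for v in c:
            mcc[v] += factorial(len(c) - 1)
    return mcc


# --- neighborhood similarity ----------------------------------------------

class TestSorensen:
    def test_identical_neighborhoods(self):
        g = nx.Graph([("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")])
        assert sorensen_similarity(g, "a", "b") == pytest.approx(1.0)

    def test_triangle_pair(self):
        g = nx.complete_graph(3)
        assert sorensen_similarity(g, 0, 1) == pytest.approx(0.5)

    def test_disjoint_neighborhoods_and_isolated_pair(self):
        g = nx.Graph([("a", "x"), ("b", "y")])
        g.add_nodes_from(["p", "q"])
        assert sorensen_similarity(g, "a", "b") == 0.0
        assert sorensen_similarity(g, "p", "q") == 0.0
        assert sorensen_distance(g, "a", "b") == 1.0


# --- hand-computed centralities -------------------------------------------

class TestHandValues:
    def test_star_graph(self):
        g = nx.star_graph(3)  # center 0, leaves 1..3
        report = compute_centralities(g, epc_iterations=10, seed=0)
        assert report.scores.loc[0, "degree"] == 3
        assert report.scores.loc[1, "degree"] == 1
        assert report.scores.loc[0, "betweenness"] == pytest.approx(3.0)
        assert report.scores.loc[1, "betweenness"] == pytest.approx(0.0)
        assert report.scores.loc[0, "stress"] == pytest.approx(3.0)

    def test_triangle_mcc_mnc_dmnc(self):
        g = nx.complete_graph(3)
        mcc = mcc_centrality(g)
        assert all(v == pytest.approx(2.0) for v in mcc.values())  # (3-1)!
        mnc, dmnc = mnc_dmnc(g)
        assert all(v == 2 for v in mnc.values())
        assert all(v == pytest.approx(1 / 2**1.7) for v in dmnc.values())

    def test_path_closeness_and_radiality(self):
        g = nx.path_graph(3)  # a-b-c as 0-1-2
        report = compute_centralities(g, epc_iterations=10, seed=0)
        assert report.scores.loc[1, "closeness"] == pytest.approx(2.0)
        assert report.scores.loc[0, "closeness"] == pytest.approx(1.5)
        rad = radiality_centrality(g)
        assert rad[1] == pytest.approx(2.0)

    def test_triangle_free_mcc_equals_degree(self):
        g = nx.star_graph(4)
        mcc = mcc_centrality(g)
        assert mcc[0] == pytest.approx(4.0)  # four isolated-edge cliques
        g.add_node("isolated")
        assert mcc_centrality(g)["isolated"] == 0.0


class TestEPC:
    def test_full_retention_counts_component_size(self):
        g = nx.erdos_renyi_graph(12, 0.4, seed=3)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        epc = epc_centrality(g, iterations=3, seed=1, retention=1.0)
        n = g.number_of_nodes()
        assert all(v == pytest.approx(n - 1) for v in epc.values())

    def test_zero_retention_gives_zero(self):
        g = nx.complete_graph(5)
        epc = epc_centrality(g, iterations=3, seed=1, retention=0.0)
        assert all(v == 0.0 for v in epc.values())

    def test_edge_addition_never_decreases_epc(self):
        g = nx.erdos_renyi_graph(10, 0.3, seed=5)
        missing = [
            (a, b) for a, b in combinations(g.nodes, 2) if not g.has_edge(a, b)
        ]
        before = epc_centrality(g, iterations=1000, seed=42)
        g2 = g.copy()
        g2.add_edge(*missing[0])
        after = epc_centrality(g2, iterations=1000, seed=42)
        # retention uniforms are keyed per node pair, so the comparison is
        # exact, not statistical
        for v in g.nodes:
            assert after[v] >= before[v] - 1e-12

    def test_invalid_iteration_count(self):
        with pytest.raises(ConfigurationError):
            epc_centrality(nx.path_graph(3), iterations=0)


class TestOracleEquivalence:
    def test_betweenness_and_stress_match_path_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(4, 10))
            g = nx.gnp_random_graph(n, rng.uniform(0.25, 0.7), seed=int(rng.integers(1 << 30)))
            report = compute_centralities(g, epc_iterations=1, seed=0)
            bet, stress = brute_force_betweenness_stress(g)
            for v in g.nodes:
                assert report.scores.loc[v, "betweenness"] == pytest.approx(bet[v])
                assert report.scores.loc[v, "stress"] == pytest.approx(stress[v])

    def test_mcc_matches_exhaustive_clique_enumeration(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=int(rng.integers(1 << 30)))
            mcc = mcc_centrality(g)
            oracle = brute_force_mcc(g)
            for v in g.nodes:
                assert mcc[v] == pytest.approx(oracle[v])

    def test_isomorphism_equivariance(self):
        g = nx.gnp_random_graph(12, 0.4, seed=9)
        mapping = {v: f"node_{(v * 7) % 12}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        rg = compute_centralities(g, epc_iterations=200, seed=3)
        rh = compute_centralities(h, epc_iterations=200, seed=3)
        for measure in ("degree", "closeness", "betweenness", "stress", "radiality",
                        "mnc", "dmnc", "mcc"):
            for v in g.nodes:
                assert rg.scores.loc[v, measure] == pytest.approx(
                    rh.scores.loc[mapping[v], measure]
                )


class TestConsensusHubs:
    def test_planted_hubs_are_top_ranked(self):
        genes = [f"G{i:03d}" for i in range(100)]
        hubs = genes[:5]
        g = generate_ppi_graph(genes, hubs, background_degree=4, hub_degree=40, seed=4)
        report = compute_centralities(g, epc_iterations=100, seed=0)
        selected = consensus_hubs(
            report, measures=("degree", "closeness", "betweenness"), top_m=5
        )
        assert set(selected) == set(hubs)

    def test_star_center_by_degree(self):
        report = compute_centralities(nx.star_graph(3), epc_iterations=10, seed=0)
        assert consensus_hubs(report, measures=("degree",), top_m=1) == [0]

    def test_tie_break_is_lexicographic(self):
        g = nx.Graph([("b", "c"), ("a", "c")])  # a and b isomorphic leaves
        report = compute_centralities(g, epc_iterations=50, seed=0)
        selected = consensus_hubs(report, measures=("degree",), top_m=3)
        assert selected.index("a") < selected.index("b")

    def test_unknown_measure_rejected(self):
        report = compute_centralities(nx.path_graph(3), epc_iterations=10, seed=0)
        with pytest.raises(ConfigurationError, match="unknown measure"):
            consensus_hubs(report, measures=("pagerank",), top_m=1)


class TestMCODE:
    def test_clique_detected_path_discarded(self):
        g = nx.complete_graph(6)
        g = nx.disjoint_union(g, nx.path_graph(4))
        result = mcode_clusters(g)
        assert len(result.clusters) == 1
        members, score = result.clusters[0]
        assert len(members) == 6
        assert score == pytest.approx(6.0)  # density 1.0 x size 6

    def test_edgeless_graph_has_no_clusters(self):
        g = nx.empty_graph(5)
        assert mcode_clusters(g).clusters == []

    def test_two_disjoint_cliques_score_equally(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        result = mcode_clusters(g)
        assert len(result.clusters) == 2
        assert result.clusters[0][1] == pytest.approx(result.clusters[1][1])
        assert all(len(m) == 5 for m, _ in result.clusters)
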