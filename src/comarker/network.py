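"""Topological hub scoring and dense-module detection on PPI networks.

Implements the CytoHubba family of node centralities — degree, closeness
(reciprocal-distance sum), betweenness, stress, radiality, MNC, DMNC, MCC
and EPC — together with rank-based consensus hub selection and MCODE-style
seed-and-grow dense-cluster detection. Graphs are simple undirected
``networkx.Graph`` objects.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .expression import ConfigurationError

MEASURES = (
    "degree",
    "closeness",
    "betweenness",
    "stress",
    "radiality",
    "mnc",
    "dmnc",
    "mcc",
    "epc",
)

DMNC_EPSILON = 1.7


def validate_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ConfigurationError("PPI graph must be a simple undirected graph")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ConfigurationError(f"PPI graph contains self-loops: {loops[:3]}")


def sorensen_similarity(graph: nx.Graph, a, b) -> float:
    """Neighborhood-overlap (Sørensen–Dice) similarity 2|Na∩Nb|/(|Na|+|Nb|).

    1.0 for identical nonempty neighborhoods, 0.0 for disjoint ones; a pair
    of isolated nodes scores 0 by convention. The complementary quantity is
    available as :func:`sorensen_distance`.
    """
    na, nb = set(graph[a]), set(graph[b])
    denom = len(na) + len(nb)
    if denom == 0:
        return 0.0
    return 2.0 * len(na & nb) / denom


def sorensen_distance(graph: nx.Graph, a, b) -> float:
    return 1.0 - sorensen_similarity(graph, a, b)


@dataclass
class CentralityReport:
    """Per-node scores for the nine measures plus dense ranks (1 = best)."""

    scores: pd.DataFrame  # nodes x MEASURES
    ranks: pd.DataFrame  # nodes x MEASURES, dense rank, higher score = rank 1

    @property
    def nodes(self) -> list:
        return list(self.scores.index)


@dataclass
class MCODEResult:
    clusters: list[tuple[list, float]]  # (member nodes, score = density * size)
    node_weights: dict


def _bfs_counts(adj: list[list[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (unweighted BFS)."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0.0
    sigma[source] = 1.0
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if dist[w] == np.inf:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def stress_centrality(graph: nx.Graph) -> dict:
    """Stress(v) = number of shortest s-t paths passing through v, summed
    over unordered pairs {s, t} with s != v != t."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[idx[w] for w in graph[v]] for v in nodes]
    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for i in range(n):
        dist[i], sigma[i] = _bfs_counts(adj, i, n)
    stress = {}
    for vi, v in enumerate(nodes):
        # paths s -> t through v: d(s,v) + d(v,t) == d(s,t), count sigma_sv * sigma_vt
        with np.errstate(invalid="ignore"):
            on_path = (dist[:, vi][:, None] + dist[vi, :][None, :]) == dist
        contrib = np.outer(sigma[:, vi], sigma[vi, :]) * on_path
        contrib[vi, :] = 0.0
        contrib[:, vi] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = float(contrib.sum() / 2.0)
    return stress


def radiality_centrality(graph: nx.Graph) -> dict:
    """Radiality(v) = sum over reachable w of (diam + 1 - d(v,w)) / (n_C - 1),
    computed within v's connected component (0 for isolated nodes)."""
    rad = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        nc = len(comp)
        if nc == 1:
            rad[next(iter(comp))] = 0.0
            continue
        dists = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            total = sum(diam + 1 - d for w, d in dists[v].items() if w != v)
            rad[v] = total / (nc - 1)
    return rad


def mnc_dmnc(graph: nx.Graph) -> tuple[dict, dict]:
    """MNC(v): size of the largest connected component of the subgraph
    induced on N(v); DMNC(v): its edge count / size**1.7 (0 below 2 nodes)."""
    mnc, dmnc = {}, {}
    for v in graph.nodes:
        nbrs = list(graph[v])
        if not nbrs:
            mnc[v], dmnc[v] = 0, 0.0
            continue
        sub = graph.subgraph(nbrs)
        best = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(map(str, c))))
        mnc[v] = len(best)
        if len(best) < 2:
            dmnc[v] = 0.0
        else:
            comp = sub.subgraph(best)
            dmnc[v] = comp.number_of_edges() / len(best) ** DMNC_EPSILON
    return mnc, dmnc


def mcc_centrality(graph: nx.Graph) -> dict:
    """Maximal clique centrality: sum over maximal cliques C containing v of
    (|C| - 1)!. Size-2 maximal cliques (isolated edges) contribute 1 each,
    so a triangle-free node scores its degree; isolated nodes score 0."""
    mcc = {v: 0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        w = factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    return {v: float(s) for v, s in mcc.items()}


def _pair_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Index of unordered pair (i < j) in the upper-triangle enumeration."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def epc_centrality(
    graph: nx.Graph, iterations: int = 1000, seed: int | None = None, retention: float | None = None
) -> dict:
    """Edge-percolated component score.

    Each iteration t draws a retention probability p_t ~ U(0,1) and keeps
    every edge independently with probability p_t; EPC(v) is the mean number
    of other nodes still connected to v. Retention uniforms are drawn per
    node pair from a stream keyed by (seed, t), so adding an edge never
    perturbs the fate of existing edges — EPC is monotone under edge
    addition at a fixed seed. ``retention`` forces a fixed keep probability
    (a degenerate hook for testing; retention=1 gives EPC = component size - 1).
    """
    if iterations < 1:
        raise ConfigurationError("epc_iterations must be >= 1")
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    if n == 0:
        return {}
    ei = np.array([min(idx[a], idx[b]) for a, b in graph.edges], dtype=np.int64)
    ej = np.array([max(idx[a], idx[b]) for a, b in graph.edges], dtype=np.int64)
    pair_idx = _pair_index(ei, ej, n) if len(ei) else np.empty(0, dtype=np.int64)
    n_pairs = n * (n - 1) // 2
    totals = np.zeros(n)
    base = np.random.SeedSequence(seed if seed is not None else 0)
    p_rng = np.random.default_rng(base.spawn(1)[0]) if retention is None else None
    for t in range(iterations):
        rng_t = np.random.default_rng(np.random.SeedSequence([base.entropy, t]))
        u = rng_t.random(n_pairs)
        p_t = p_rng.random() if retention is None else retention
        keep = u[pair_idx] < p_t if len(pair_idx) else np.empty(0, dtype=bool)
        mat = coo_matrix(
            (np.ones(int(keep.sum())), (ei[keep], ej[keep])), shape=(n, n)
        )
        _, labels = connected_components(mat, directed=False)
        sizes = np.bincount(labels, minlength=labels.max() + 1)
        totals += sizes[labels] - 1
    return {v: float(totals[idx[v]] / iterations) for v in nodes}


def compute_centralities(
    graph: nx.Graph, epc_iterations: int = 1000, seed: int | None = None
) -> CentralityReport:
    """Score every node with the nine topological measures and dense-rank
    each measure (rank 1 = highest score)."""
    validate_simple(graph)
    if graph.number_of_nodes() == 0:
        raise ConfigurationError("graph is empty")
    nodes = list(graph.nodes)
    mnc, dmnc = mnc_dmnc(graph)
    scores = pd.DataFrame(
        {
            "degree": pd.Series(dict(graph.degree), dtype=float),
            "closeness": pd.Series(nx.harmonic_centrality(graph), dtype=float),
            "betweenness": pd.Series(
                nx.betweenness_centrality(graph, normalized=False), dtype=float
            ),
            "stress": pd.Series(stress_centrality(graph), dtype=float),
            "radiality": pd.Series(radiality_centrality(graph), dtype=float),
            "mnc": pd.Series(mnc, dtype=float),
            "dmnc": pd.Series(dmnc, dtype=float),
            "mcc": pd.Series(mcc_centrality(graph), dtype=float),
            "epc": pd.Series(
                epc_centrality(graph, iterations=epc_iterations, seed=seed), dtype=float
            ),
        }
    ).loc[nodes]
    ranks = scores.rank(method="dense", ascending=False).astype(int)
    return CentralityReport(scores=scores, ranks=ranks)


DEFAULT_CONSENSUS_MEASURES = (
    "degree",
    "closeness",
    "epc",
    "mnc",
    "betweenness",
    "radiality",
    "stress",
)


def consensus_hubs(
    report: CentralityReport,
    measures: tuple[str, ...] = DEFAULT_CONSENSUS_MEASURES,
    top_m: int = 6,
    mode: str = "intersection",
) -> list:
    """Consensus hub genes across several centrality measures.

    ``intersection`` mode takes nodes ranked within the top ``top_m`` by
    every selected measure, ordered by mean rank (ties lexicographic); when
    the intersection is short, the list is completed by ascending mean rank.
    ``union`` mode pools the per-measure top sets instead.
    """
    if not measures:
        raise ConfigurationError("measures must be nonempty")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ConfigurationError(f"unknown measure name(s): {sorted(unknown)}")
    if top_m < 1:
        raise ConfigurationError("top_m must be >= 1")
    if mode not in ("intersection", "union"):
        raise ConfigurationError("mode must be 'intersection' or 'union'")
    ranks = report.ranks[list(measures)]
    mean_rank = ranks.mean(axis=1)
    order = sorted(report.nodes, key=lambda v: (mean_rank[v], str(v)))
    top_sets = [set(ranks.index[ranks[m] <= top_m]) for m in measures]
    pool = set.intersection(*top_sets) if mode == "intersection" else set.union(*top_sets)
    selected = [v for v in order if v in pool]
    if len(selected) < top_m:
        selected = order
    return selected[:top_m]


def _core_weight(graph: nx.Graph, v) -> float:
    """MCODE vertex weight: highest-k-core number of the closed neighborhood
    graph times the density of that k-core."""
    nbhd = list(graph[v]) + [v]
    sub = nx.Graph(graph.subgraph(nbhd))
    sub.remove_edges_from(nx.selfloop_edges(sub))
    if sub.number_of_edges() == 0:
        return 0.0
    core_nums = nx.core_number(sub)
    k = max(core_nums.values())
    core = sub.subgraph([u for u, c in core_nums.items() if c >= k])
    nodes = core.number_of_nodes()
    if nodes < 2:
        return 0.0
    density = 2.0 * core.number_of_edges() / (nodes * (nodes - 1))
    return k * density


def mcode_clusters(
    graph: nx.Graph,
    vwp: float = 0.2,
    degree_cutoff: int = 2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
) -> MCODEResult:
    """MCODE seed-and-grow dense-module detection.

    Vertices are weighted by their highest-k-core neighborhood density,
    seeds are processed in descending weight, and growth admits unvisited
    neighbors whose weight is at least (1 - vwp) times the seed weight.
    Haircut removes singly-connected members, and clusters lacking a
    ``k_core``-core are discarded. Cluster score = density x size.
    """
    validate_simple(graph)
    if not 0 <= vwp < 1:
        raise ConfigurationError("vwp must be in [0, 1)")
    if fluff:
        raise ConfigurationError("fluff expansion is not implemented")
    weights = {
        v: (_core_weight(graph, v) if graph.degree[v] >= degree_cutoff else 0.0)
        for v in graph.nodes
    }
    visited: set = set()
    clusters = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop()
            for w in graph[v]:
                if w not in visited and weights[w] >= threshold:
                    visited.add(w)
                    members.add(w)
                    frontier.append(w)
        sub = graph.subgraph(members)
        if haircut:
            keep = [v for v in sub.nodes if sub.degree[v] >= 2]
            sub = graph.subgraph(keep)
        if sub.number_of_nodes() < 2:
            continue
        if k_core and nx.k_core(nx.Graph(sub), k=k_core).number_of_nodes() == 0:
            continue
        n = sub.number_of_nodes()
        density = 2.0 * sub.number_of_edges() / (n * (n - 1))
        clusters.append((sorted(sub.nodes, key=str), density * n))
    clusters.sort(key=lambda c: (-c[1], c[0]))
    return MCODEResult(clusters=clusters, node_weights=weights)
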