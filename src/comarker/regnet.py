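"""Bipartite regulator-gene networks (TF -> gene, miRNA -> gene) and key
regulator selection by degree and betweenness thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .expression import ConfigurationError, DataError

REGULATOR_KINDS = ("TF", "miRNA")


@dataclass
class BipartiteRegNet:
    """Regulator-target edges; regulators carry a kind (TF or miRNA)."""

    regulator_kinds: dict[str, str]  # regulator id -> kind
    edges: list[tuple[str, str]] = field(default_factory=list)  # (regulator, target)

    def __post_init__(self) -> None:
        bad = {k for k in self.regulator_kinds.values()} - set(REGULATOR_KINDS)
        if bad:
            raise DataError(f"unknown regulator kind(s): {sorted(bad)}")
        seen = set()
        deduped = []
        for reg, tgt in self.edges:
            if reg not in self.regulator_kinds:
                raise DataError(f"edge references unknown regulator {reg!r}")
            if reg == tgt:
                raise DataError(f"self edge {reg!r} is not a regulator-target link")
            if (reg, tgt) not in seen:
                seen.add((reg, tgt))
                deduped.append((reg, tgt))
        self.edges = deduped

    @property
    def regulators(self) -> set[str]:
        return set(self.regulator_kinds)

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def subnet(self, kind: str) -> "BipartiteRegNet":
        if kind not in REGULATOR_KINDS:
            raise ConfigurationError(f"kind must be one of {REGULATOR_KINDS}")
        kinds = {r: k for r, k in self.regulator_kinds.items() if k == kind}
        return BipartiteRegNet(
            regulator_kinds=kinds, edges=[(r, t) for r, t in self.edges if r in kinds]
        )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.regulators, bipartite="regulator")
        g.add_nodes_from(self.targets, bipartite="target")
        g.add_edges_from(self.edges)
        return g


def select_regulators(
    net: BipartiteRegNet,
    degree_min: int = 1,
    betweenness_min: float = 0.0,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank regulators by target degree and unweighted betweenness.

    Degree is the number of distinct targets; betweenness is computed on the
    bipartite graph treated as undirected and unnormalized. Regulators with
    degree >= degree_min and betweenness >= betweenness_min are returned,
    sorted by (degree desc, betweenness desc, id asc); ``top_k`` truncates.
    """
    if degree_min < 1:
        raise ConfigurationError("degree_min must be >= 1")
    if not net.edges:
        raise DataError("regulatory network has no edges")
    g = net.to_graph()
    betweenness = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for reg in sorted(net.regulators):
        deg = sum(1 for r, _ in net.edges if r == reg)
        rows.append(
            (reg, net.regulator_kinds[reg], deg, betweenness.get(reg, 0.0))
        )
    out = pd.DataFrame(rows, columns=["regulator", "kind", "degree", "betweenness"])
    out = out[(out["degree"] >= degree_min) & (out["betweenness"] >= betweenness_min)]
    out = out.sort_values(
        ["degree", "betweenness", "regulator"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k)
    return out
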