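"""Readers and writers for the plain-text formats the pipeline exchanges:
expression TSV + label sidecar, edge lists (TSV / SIF / GraphML), GMT gene
sets, affinity CSV, DEG / association tables and the synthetic truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .drugs import AffinityMatrix
from .enrichment import GeneSetCollection
from .expression import DEGTable, ExpressionStudy
from .regnet import BipartiteRegNet
from .synth import SyntheticTruth


# --- expression -----------------------------------------------------------

def write_expression(study: ExpressionStudy, expr_path, labels_path) -> None:
    study.values.to_csv(expr_path, sep="\t", index_label="gene")
    study.sample_groups.rename("group").to_csv(labels_path, sep="\t", index_label="sample")


def read_expression(expr_path, labels_path, disease_id: str, scale: str = "log2") -> ExpressionStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene")
    values.index.name = None
    groups = pd.read_csv(labels_path, sep="\t", index_col="sample")["group"]
    groups.index.name = None
    groups.name = None
    return ExpressionStudy(
        disease_id=disease_id, values=values, sample_groups=groups, scale=scale
    )


# --- networks -------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted((sorted(map(str, e)) for e in graph.edges)):
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    return g


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted((sorted(map(str, e)) for e in graph.edges)):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in sorted(map(str, nx.isolates(graph))):
            fh.write(f"{v}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                src = parts[0]
                for tgt in parts[2:]:
                    g.add_edge(src, tgt)
            elif parts and parts[0]:
                g.add_node(parts[0])
    return g


def write_graphml(graph: nx.Graph, path, scores: pd.DataFrame | None = None) -> None:
    annotated = nx.Graph(graph)
    if scores is not None:
        for measure in scores.columns:
            nx.set_node_attributes(annotated, scores[measure].to_dict(), name=measure)
    nx.write_graphml(annotated, path)


# --- gene sets ------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (name, members) in collection.sets.items():
            fh.write("\t".join([sid, name, *members]) + "\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sid, name, members = parts[0], parts[1], tuple(parts[2:])
            sets[sid] = (name, members)
            seen.update(members)
    univ = frozenset(universe) if universe is not None else frozenset(seen)
    return GeneSetCollection(sets=sets, universe=univ)


# --- affinity matrices ----------------------------------------------------

def write_affinity(matrix: AffinityMatrix, path) -> None:
    matrix.scores.to_csv(path, index_label="receptor")


def read_affinity(path, provenance: str = "") -> AffinityMatrix:
    scores = pd.read_csv(path, index_col="receptor")
    scores.index.name = None
    scores.columns.name = None
    return AffinityMatrix(scores=scores, provenance=provenance or str(path))


# --- regulators -----------------------------------------------------------

def read_regnet(path) -> BipartiteRegNet:
    df = pd.read_csv(path, sep="\t")
    kinds = dict(zip(df["regulator"], df["kind"]))
    edges = list(zip(df["regulator"], df["target"]))
    return BipartiteRegNet(regulator_kinds=kinds, edges=edges)


def write_regnet(net: BipartiteRegNet, path) -> None:
    rows = [(r, net.regulator_kinds[r], t) for r, t in net.edges]
    pd.DataFrame(rows, columns=["regulator", "kind", "target"]).to_csv(
        path, sep="\t", index=False
    )


# --- tables and truth -----------------------------------------------------

def write_deg_table(table: DEGTable, path) -> None:
    table.table.to_csv(path, sep="\t", index_label="gene")


def read_deg_table(path, disease_id: str) -> DEGTable:
    return DEGTable(disease_id=disease_id, table=pd.read_csv(path, sep="\t", index_col="gene"))


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "shared_up_genes": truth.shared_up_genes,
        "shared_down_genes": truth.shared_down_genes,
        "private_deg_genes": truth.private_deg_genes,
        "coexpression_modules": truth.coexpression_modules,
        "planted_hubs": truth.planted_hubs,
        "enriched_sets": truth.enriched_sets,
        "strong_drugs": truth.strong_drugs,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(**payload)
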