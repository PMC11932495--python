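"""Synthetic-data generators for every input the pipeline consumes.

The generators plant known structure — shared up/down-regulated gene blocks
across diseases, latent-factor co-expression modules, high-degree network
hubs, enriched annotation sets, and strong-binder drug columns — so each
downstream stage can be tested against a recorded ground truth without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .drugs import AffinityMatrix
from .enrichment import GeneSetCollection
from .expression import CASE, CONTROL, ConfigurationError, ExpressionStudy


@dataclass
class SyntheticDesign:
    """Study conditions for the planted-signal expression simulator.

    Defaults describe three case/control cohorts of 20+20 samples over a
    2000-gene universe with 30 shared up- and 40 shared down-regulated genes
    (log2-scale shift ``effect_size``), 25 private DEGs per disease, two
    latent-factor co-expression blocks, and Gaussian within-group noise.
    """

    n_genes: int = 2000
    n_diseases: int = 3
    cases_per_disease: int = 20
    controls_per_disease: int = 20
    n_shared_up: int = 30
    n_shared_down: int = 40
    n_private_deg: int = 25
    effect_size: float = 3.0
    noise_sd: float = 0.5
    module_spec: tuple[tuple[int, float], ...] = ((60, 0.8), (45, 0.8))
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    scale: str = "log2"
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.n_shared_up
            + self.n_shared_down
            + self.n_diseases * self.n_private_deg
            + sum(size for size, _ in self.module_spec)
        )
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be > 0 (0 allowed for null designs)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        for size, rho in self.module_spec:
            if not 0 <= rho < 1:
                raise ConfigurationError(f"latent_correlation must be in [0,1), got {rho}")
            if size < 2:
                raise ConfigurationError("module sizes must be >= 2")
        if self.n_diseases < 1 or self.n_genes < 1:
            raise ConfigurationError("n_diseases and n_genes must be >= 1")
        if self.cases_per_disease < 2 or self.controls_per_disease < 2:
            raise ConfigurationError("need >= 2 cases and >= 2 controls per disease")
        if self.scale not in ("log2", "linear"):
            raise ConfigurationError("scale must be 'log2' or 'linear'")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside the generated artifacts."""

    shared_up_genes: list[str] = field(default_factory=list)
    shared_down_genes: list[str] = field(default_factory=list)
    private_deg_genes: dict[str, list[str]] = field(default_factory=dict)
    coexpression_modules: list[list[str]] = field(default_factory=list)
    planted_hubs: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    strong_drugs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.shared_up_genes) & set(self.shared_down_genes):
            raise ConfigurationError("shared up and down gene lists overlap")


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def disease_ids(n_diseases: int) -> list[str]:
    return [f"D{i}" for i in range(1, n_diseases + 1)]


def generate_expression_studies(
    design: SyntheticDesign,
) -> tuple[list[ExpressionStudy], SyntheticTruth]:
    """Generate one case/control study per disease plus the planted truth.

    Planted shared-up genes carry a +effect_size case-minus-control mean
    shift in every disease (shared-down genes -effect_size); private DEGs
    are shifted in one disease only (alternating direction); co-expression
    blocks follow x = sqrt(rho) f + sqrt(1-rho) eps so every within-block
    gene pair has expected correlation rho. All simulation is on log2 scale;
    ``scale='linear'`` exponentiates the written matrices.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = gene_universe(design.n_genes)
    diseases = disease_ids(design.n_diseases)

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor : cursor + k]
        cursor += k
        return block

    up = take(design.n_shared_up)
    down = take(design.n_shared_down)
    private = {d: take(design.n_private_deg) for d in diseases}
    modules = [take(size) for size, _ in design.module_spec]

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_case, n_ctrl = design.cases_per_disease, design.controls_per_disease
    n_samples = n_case + n_ctrl

    studies = []
    for d in diseases:
        x = baseline[:, None] + rng.normal(0.0, design.noise_sd, size=(design.n_genes, n_samples))
        case_cols = np.arange(n_samples) < n_case
        for g in up:
            x[gene_pos[g], case_cols] += design.effect_size
        for g in down:
            x[gene_pos[g], case_cols] -= design.effect_size
        for j, g in enumerate(private[d]):
            sign = 1.0 if j % 2 == 0 else -1.0
            x[gene_pos[g], case_cols] += sign * design.effect_size
        for (size, rho), members in zip(design.module_spec, modules):
            latent = rng.normal(0.0, 1.0, size=n_samples)
            rows = [gene_pos[g] for g in members]
            eps = rng.normal(0.0, 1.0, size=(size, n_samples))
            x[rows, :] = (
                baseline[rows, None]
                + design.noise_sd * (np.sqrt(rho) * latent[None, :] + np.sqrt(1.0 - rho) * eps)
            )
        samples = [f"{d}_case_{i + 1}" for i in range(n_case)] + [
            f"{d}_ctrl_{i + 1}" for i in range(n_ctrl)
        ]
        groups = pd.Series([CASE] * n_case + [CONTROL] * n_ctrl, index=samples)
        values = pd.DataFrame(x, index=genes, columns=samples)
        if design.scale == "linear":
            values = np.exp2(values)
        studies.append(
            ExpressionStudy(disease_id=d, values=values, sample_groups=groups, scale=design.scale)
        )

    truth = SyntheticTruth(
        shared_up_genes=up,
        shared_down_genes=down,
        private_deg_genes=private,
        coexpression_modules=modules,
    )
    return studies, truth


def generate_ppi_graph(
    gene_universe: list[str],
    planted_hubs: list[str],
    background_degree: int = 4,
    hub_degree: int = 40,
    seed: int = 0,
) -> nx.Graph:
    """Erdős–Rényi background network with planted high-degree hubs.

    Background edges appear with probability background_degree/(n-1); each
    planted hub is additionally wired to ``hub_degree`` distinct random
    partners. The result is simple and undirected.
    """
    n = len(gene_universe)
    if len(set(gene_universe)) != n:
        raise ConfigurationError("gene_universe contains duplicate ids")
    if not set(planted_hubs) <= set(gene_universe):
        raise ConfigurationError("planted_hubs must be a subset of gene_universe")
    if hub_degree >= n:
        raise ConfigurationError(f"hub_degree ({hub_degree}) must be < |gene_universe| ({n})")
    if planted_hubs and hub_degree <= background_degree:
        raise ConfigurationError("hub_degree must exceed background_degree")
    rng = np.random.default_rng(seed)
    p = min(1.0, background_degree / max(n - 1, 1))
    g = nx.Graph()
    g.add_nodes_from(gene_universe)
    nodes = list(gene_universe)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    for i, j in zip(*np.nonzero(upper)):
        g.add_edge(nodes[i], nodes[j])
    for hub in planted_hubs:
        others = [v for v in nodes if v != hub]
        partners = rng.choice(len(others), size=hub_degree, replace=False)
        for idx in partners:
            g.add_edge(hub, others[idx])
    return g


def generate_gene_sets(
    gene_universe: list[str],
    target_genes: list[str],
    n_enriched: int = 5,
    n_background: int = 50,
    set_size: int = 50,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str]]:
    """Annotation collection with ``n_enriched`` sets planted around
    ``target_genes`` plus uniform background sets; returns the collection and
    the planted set ids."""
    if len(set(gene_universe)) != len(gene_universe):
        raise ConfigurationError("gene_universe contains duplicate ids")
    if set_size > len(gene_universe):
        raise ConfigurationError("set_size exceeds the gene universe")
    if not set(target_genes) <= set(gene_universe):
        raise ConfigurationError("target_genes must be a subset of gene_universe")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    others = [g for g in universe if g not in set(target_genes)]
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    enriched_ids = []
    for i in range(1, n_enriched + 1):
        sid = f"ENR{i:03d}"
        core = list(target_genes)[: set_size]
        fill_n = set_size - len(core)
        fill = rng.choice(len(others), size=fill_n, replace=False) if fill_n else []
        members = tuple(core + [others[j] for j in fill])
        sets[sid] = (f"planted enriched set {i}", members)
        enriched_ids.append(sid)
    for i in range(1, n_background + 1):
        sid = f"BG{i:03d}"
        members = rng.choice(len(universe), size=set_size, replace=False)
        sets[sid] = (f"background set {i}", tuple(universe[j] for j in members))
    return GeneSetCollection(sets=sets, universe=frozenset(universe)), enriched_ids


def generate_affinity_matrix(
    n_receptors: int = 8,
    n_drugs: int = 60,
    n_strong_drugs: int = 7,
    strong_mean: float = -9.0,
    background_mean: float = -5.0,
    sd: float = 0.3,
    seed: int = 0,
    provenance: str = "synthetic",
    strong_drugs: list[str] | None = None,
) -> tuple[AffinityMatrix, list[str]]:
    """Receptor x drug binding-score matrix (kcal/mol, negative = stronger)
    with a planted block of strong binders; returns the matrix and the
    planted drug ids. ``strong_drugs`` pins the planted columns (used for
    validation panels that must share the discovery panel's true binders)."""
    if n_strong_drugs > n_drugs:
        raise ConfigurationError("n_strong_drugs cannot exceed n_drugs")
    if strong_mean >= background_mean:
        raise ConfigurationError("strong_mean must be more negative than background_mean")
    rng = np.random.default_rng(seed)
    receptors = [f"R{i:02d}" for i in range(1, n_receptors + 1)]
    drugs = [f"DRUG{i:03d}" for i in range(1, n_drugs + 1)]
    if strong_drugs is not None:
        if not set(strong_drugs) <= set(drugs):
            raise ConfigurationError("strong_drugs must name existing drug columns")
        strong = sorted(drugs.index(d) for d in strong_drugs)
    else:
        strong = sorted(rng.choice(n_drugs, size=n_strong_drugs, replace=False).tolist())
    means = np.full(n_drugs, background_mean)
    means[strong] = strong_mean
    scores = means[None, :] + rng.normal(0.0, sd, size=(n_receptors, n_drugs)) if sd > 0 else (
        np.tile(means, (n_receptors, 1))
    )
    matrix = AffinityMatrix(
        scores=pd.DataFrame(scores, index=receptors, columns=drugs),
        provenance=provenance,
    )
    return matrix, [drugs[i] for i in strong]
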