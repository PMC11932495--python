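"""End-to-end orchestration of the discovery pipeline on synthetic cohorts.

Runs every stage in order — expression simulation, per-disease module-
filtered DEG calling, cross-disease intersection and association, PPI hub
consensus, enrichment of the hub panel, and affinity-matrix drug selection
— and scores each stage against the planted truth. This is the entry point
the acceptance machinery and the worked example use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CDEGSet, intersect_degs, local_association
from .drugs import AffinityMatrix, cross_validate_leads, select_lead_drugs
from .enrichment import fisher_enrich
from .expression import DEGStageParams, DEGTable, run_deg_stage
from .network import CentralityReport, compute_centralities, consensus_hubs
from .synth import (
    SyntheticDesign,
    SyntheticTruth,
    generate_affinity_matrix,
    generate_expression_studies,
    generate_gene_sets,
    generate_ppi_graph,
)


@dataclass
class PipelineResult:
    truth: SyntheticTruth
    deg_tables: list[DEGTable]
    cdegs: CDEGSet
    association: pd.DataFrame
    centrality: CentralityReport
    hubs: list[str]
    enrichment: pd.DataFrame
    affinity: AffinityMatrix
    lead_drugs: list[str]
    cross_validation: pd.DataFrame
    metrics: dict[str, float] = field(default_factory=dict)


def run_synthetic_pipeline(
    design: SyntheticDesign | None = None,
    deg_params: DEGStageParams | None = None,
    n_hubs: int = 5,
    hub_degree: int = 40,
    background_degree: int = 4,
    hub_measures: tuple[str, ...] = ("degree", "closeness", "betweenness"),
    epc_iterations: int = 500,
    n_enriched_sets: int = 5,
    n_background_sets: int = 50,
    gene_set_size: int = 50,
    n_receptors: int = 8,
    n_drugs: int = 60,
    n_strong_drugs: int = 7,
    n_validation_panels: int = 3,
    affinity_threshold: float = -7.0,
) -> PipelineResult:
    """Run the full pipeline on one synthetic study bundle.

    The PPI network is built over the recovered cDEG panel (hubs planted
    among the true shared-up genes), the enrichment query is the consensus
    hub list, and the affinity matrices carry a planted strong-binder block.
    Recovery metrics against the planted truth are collected in
    ``result.metrics``.
    """
    design = design or SyntheticDesign()
    studies, truth = generate_expression_studies(design)
    seed = design.seed

    deg_tables = []
    for study in studies:
        table, _, _ = run_deg_stage(study, deg_params)
        deg_tables.append(table)

    cdegs = intersect_degs(deg_tables)
    assoc = local_association(cdegs)

    # PPI over the cDEG panel; hubs planted among true shared-up genes
    panel = sorted(set(cdegs.genes) | set(truth.shared_up_genes))
    truth.planted_hubs = truth.shared_up_genes[:n_hubs]
    graph = generate_ppi_graph(
        panel,
        truth.planted_hubs,
        background_degree=background_degree,
        hub_degree=min(hub_degree, len(panel) - 1),
        seed=seed + 1,
    )
    report = compute_centralities(graph, epc_iterations=epc_iterations, seed=seed + 2)
    hubs = consensus_hubs(report, measures=hub_measures, top_m=n_hubs)

    collection, enriched_ids = generate_gene_sets(
        [f"G{i:06d}" for i in range(1, design.n_genes + 1)],
        target_genes=hubs,
        n_enriched=n_enriched_sets,
        n_background=n_background_sets,
        set_size=gene_set_size,
        seed=seed + 3,
    )
    truth.enriched_sets = enriched_ids
    enrich = fisher_enrich(hubs, collection)

    affinity, strong = generate_affinity_matrix(
        n_receptors=n_receptors,
        n_drugs=n_drugs,
        n_strong_drugs=n_strong_drugs,
        seed=seed + 4,
    )
    truth.strong_drugs = strong
    leads = select_lead_drugs(affinity, threshold=affinity_threshold)
    # independent receptor panels share the true binders by construction
    panels = [
        generate_affinity_matrix(
            n_receptors=n_receptors,
            n_drugs=n_drugs,
            n_strong_drugs=n_strong_drugs,
            seed=seed + 5 + i,
            provenance=f"validation{i + 1}",
            strong_drugs=strong,
        )[0]
        for i in range(n_validation_panels)
    ]
    xval = cross_validate_leads(leads, panels, threshold=affinity_threshold) if leads else (
        pd.DataFrame(columns=["drug", "panel", "pass_fraction", "binds_most"])
    )

    metrics = _score_against_truth(truth, deg_tables, cdegs, assoc, hubs, enrich, leads)
    return PipelineResult(
        truth=truth,
        deg_tables=deg_tables,
        cdegs=cdegs,
        association=assoc,
        centrality=report,
        hubs=hubs,
        enrichment=enrich,
        affinity=affinity,
        lead_drugs=leads,
        cross_validation=xval,
        metrics=metrics,
    )


def _score_against_truth(
    truth: SyntheticTruth,
    deg_tables: list[DEGTable],
    cdegs: CDEGSet,
    assoc: pd.DataFrame,
    hubs: list[str],
    enrich: pd.DataFrame,
    leads: list[str],
) -> dict[str, float]:
    up, down = set(truth.shared_up_genes), set(truth.shared_down_genes)
    recovered = (len(up & set(cdegs.up)) + len(down & set(cdegs.down))) / max(
        len(up) + len(down), 1
    )
    offdiag = assoc.to_numpy()[~np.eye(len(assoc), dtype=bool)]
    planted = set(truth.enriched_sets)
    ordered = list(enrich["set_id"])
    worst_planted = max(ordered.index(s) for s in planted) if planted else -1
    best_background = min(
        (i for i, s in enumerate(ordered) if s not in planted), default=len(ordered)
    )
    return {
        "n_cdegs_up": float(len(cdegs.up)),
        "n_cdegs_down": float(len(cdegs.down)),
        "shared_deg_recovery": float(recovered),
        "hub_recovery": float(len(set(hubs) & set(truth.planted_hubs)) / max(len(truth.planted_hubs), 1)),
        "min_association_r": float(offdiag.min()) if offdiag.size else float("nan"),
        "enrichment_separation": float(worst_planted < best_background),
        "lead_drug_jaccard": float(
            len(set(leads) & set(truth.strong_drugs))
            / max(len(set(leads) | set(truth.strong_drugs)), 1)
        ),
        "n_lead_drugs": float(len(leads)),
    }
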