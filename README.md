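# comarker

Cross-disease transcriptomic biomarker discovery and shared drug
prioritization.

When several diseases co-occur in the same patients (for example a
metabolic disorder alongside two cancers), genes that are differentially
expressed *in the same direction in every disease* point at shared
pathogenetic mechanisms — and at drug targets that could treat the
comorbidity with a single compound instead of one drug per disease.
`comarker` implements that discovery chain as a tested, reusable pipeline
for anyone with case/control expression matrices from two or more cohorts:

1. **Differential expression with a co-expression filter.** Per gene, the
   average log2 fold-change
   `aLog2FC_g = mean(log2 x_case) − mean(log2 x_control)`; genes are kept
   only if they belong to a co-expression module (WGCNA-style: unsigned
   adjacency `|cor|^β` with β chosen by scale-free fit, topological-overlap
   clustering) whose eigengene correlates with disease status
   (`|r| ≥ 0.6`, `p < 0.001` by default). UR/DR calls use strict
   thresholds `aLog2FC > 1` / `< −1`.
2. **Common DEGs and local genetic association.** Genes up-regulated in
   every disease union genes down-regulated in every disease, and the
   pairwise Pearson correlation of the per-disease `aLog2FC` vectors over
   that common panel.
3. **Hub-gene consensus on a PPI network.** Nine node centralities
   implemented from their definitions (degree, reciprocal-distance
   closeness, betweenness, stress, radiality, MNC, DMNC with ε = 1.7, MCC
   as Σ(|clique|−1)! over maximal cliques, and an edge-percolation EPC),
   combined by rank intersection/union; MCODE seed-and-grow detection of
   dense modules.
4. **Enrichment.** One-sided Fisher exact test (hypergeometric upper tail)
   of the hub panel against annotation sets, Benjamini–Hochberg FDR, and
   an optional `−ln(p)·z` combined score.
5. **Regulators.** Degree/betweenness selection of TFs and miRNAs from
   bipartite regulator–gene networks.
6. **Drug prioritization.** Receptor × drug binding-affinity matrices
   (kcal/mol) ranked by row/column means, an all-receptor strong-binding
   rule (every score strictly below −7.0 kcal/mol), cross-validation
   against independent receptor panels, Lipinski rule-of-five screening,
   and conceptual-DFT reactivity descriptors from HOMO/LUMO energies
   (ΔE = E_LUMO − E_HOMO, I = −E_HOMO, A = −E_LUMO, η = (I−A)/2,
   σ = 1/η, χ = (I+A)/2, μ = −χ).

A first-class synthetic-data module generates every input with planted
ground truth (shared DEG blocks, latent-factor co-expression modules,
network hubs, enriched sets, strong-binder drugs), so the entire chain is
testable end to end without any external database.

## Worked example

```python
from comarker import SyntheticDesign, run_synthetic_pipeline

res = run_synthetic_pipeline(SyntheticDesign(seed=7))
print("common DEGs: %d up, %d down" % (len(res.cdegs.up), len(res.cdegs.down)))
print(res.association.round(3))
print("consensus hubs:", ", ".join(res.hubs))
print("lead drugs:", ", ".join(res.lead_drugs))
```

prints

```
common DEGs: 30 up, 40 down
       D1     D2     D3
D1  1.000  0.997  0.998
D2  0.997  1.000  0.998
D3  0.998  0.998  1.000
consensus hubs: G000002, G000005, G000001, G000004, G000003
lead drugs: DRUG043, DRUG055, DRUG008, DRUG029, DRUG035, DRUG036, DRUG045
```

The three cohorts carry 30 planted shared-up and 40 shared-down genes —
the pipeline recovers all 70 with the correct direction. The association
matrix shows the strong cross-disease correlation the shared effects
induce. The five consensus hubs are exactly the five planted high-degree
nodes, and the seven lead drugs are exactly the seven planted strong
binders.

The same stages are available from the shell:

```
comarker synth --config design.yaml --out bundle/ --seed 3
comarker deg --expr bundle/D1_expr.tsv --labels bundle/D1_labels.tsv --out d1_deg.tsv
comarker cdeg --deg d1_deg.tsv --deg d2_deg.tsv --out-cdegs cdegs.tsv --out-association assoc.csv
comarker hubs --edges bundle/ppi_edges.tsv --top 6 --out centralities.tsv
comarker enrich --gmt bundle/gene_sets.gmt --query hubs.txt --out enrich.tsv
comarker drugs --affinity bundle/affinity.csv --threshold -7.0 --out leads.tsv
comarker dft --orbitals homo_lumo.csv --out descriptors.csv
```

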