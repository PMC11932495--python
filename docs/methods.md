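# Methods

## Differential expression

For a study with case samples `i = 1..n1` and control samples `j = 1..n2`,
the per-gene statistic is the average log2 fold-change

    aLog2FC_g = (1/n1) Σ_i log2 z_gi^case − (1/n2) Σ_j log2 z_gj^control.

The paired form sometimes written for equal group sizes,
`(1/n) Σ_i log2(z_gi^case / z_gi^control)`, is algebraically the same
difference of means, so a single branch implements both; a unit test
asserts the identity. Matrices may be supplied on log2 scale (typical for
normalized microarray data) or on linear scale, in which case log2 is
taken internally and nonpositive values are rejected with the offending
gene and sample named. UR/DR calls use strict thresholds
(`aLog2FC > 1`, `< −1`); a value of exactly 1 is not significant.

## Co-expression module filter

Genes that pass the fold-change thresholds but do not co-vary as a
disease-linked module are treated as noise. The filter is WGCNA-flavored:

- **Network.** Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` (Pearson).
  β is the smallest candidate whose connectivity distribution fits a
  scale-free law at R² ≥ 0.84 (R² of log10 binned frequency vs log10 mean
  connectivity, 10 bins); if none reaches the cutoff, the best-fitting β
  is used and flagged. Zero-variance genes are excluded with a warning.
- **Topological overlap.**
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  `TOM_ii = 1`; modules come from average-linkage hierarchical clustering
  of `1 − TOM`.
- **Tree cut.** A static cut at dissimilarity 0.95 (configurable), with
  clusters below the minimum size (default 30) labelled unassigned. A cut
  placed at a high quantile of the merge heights was rejected: with
  average linkage on `1 − TOM`, merges among noise genes concentrate just
  below 1.0, so a quantile-based cut lands above the noise band and
  returns a single giant module. A fixed cut below that band separates
  genuine modules (whose internal dissimilarities are far lower) from
  noise, which ends up in singletons and small clusters. This static
  cut + minimum-size rule stands in for dynamic tree cutting; it is
  deterministic and honest about its two parameters.
- **Eigengene.** First principal component of the module's standardized
  expression (unit norm per sample), sign-oriented to correlate
  positively with the module's mean profile. Modules whose eigengenes are
  closer than the merge height (default `1 − cor < 0.17`) are merged
  iteratively, closest pair first.
- **Trait filter.** Modules are retained when the eigengene/trait Pearson
  correlation satisfies `|r| ≥ 0.6` and the two-sided t-test
  `t = r sqrt((n−2)/(1−r²))` gives `p < 0.001`. Under a pure-noise module
  this retention event is rare (measured rate 0 in 1000 null replicates
  at n = 40; the |r| ≥ 0.6 requirement alone sits at ≈ 4·10⁻⁵).

The upstream expression pre-filter used by some published workflows is
replaced by an optional variance filter (default: keep all genes); the
module filter itself is what carries the noise rejection here.

## Common DEGs and association

`cDEGs = (∩ UR sets) ∪ (∩ DR sets)` — a gene must be called with the same
direction in *every* disease; genes significant in some diseases only, or
with conflicting directions, are excluded entirely. The local genetic
association between diseases A and B is the Pearson correlation of their
aLog2FC vectors over the sorted cDEG panel (identical gene ordering on
both sides — correlation is pairing-sensitive). No significance procedure
is attached to these correlations. Zero-variance vectors produce NaN with
a warning, never a silent 0.

## Centralities

All nine measures are computed from their definitions on a simple
undirected graph:

- degree; **closeness** as Σ 1/d(v,w) (reciprocal-distance convention,
  which stays finite on disconnected graphs); **betweenness**
  Σ σ_st(v)/σ_st and **stress** Σ σ_st(v), both over unordered pairs,
  unnormalized; **radiality** Σ (diam_C + 1 − d(v,w)) / (n_C − 1) within
  v's component.
- **MNC**: size of the largest connected component of the open
  neighborhood subgraph; **DMNC**: its edge count divided by its size
  raised to ε = 1.7 (0 when below 2 nodes).
- **MCC**: Σ (|C|−1)! over maximal cliques C ∋ v of size ≥ 2. A node
  whose edges lie in no triangle therefore scores its degree (each
  isolated edge is a maximal 2-clique worth 1); isolated nodes score 0.
- **EPC**: over T iterations (default 1000), a retention probability
  p_t ~ U(0,1) is drawn, every edge is kept independently with
  probability p_t, and the number of nodes still connected to v is
  averaged. Retention uniforms are drawn per *node pair* from a stream
  keyed by (seed, iteration), so adding an edge never changes the fate of
  existing edges; EPC is then monotone under edge addition exactly, not
  just in expectation, which the property suite exploits. The percolation
  scheme is an explicit, seeded approximation of the measure as used by
  common hub-ranking tools, whose exact scheme is not published in full.

Consensus hubs: per measure, dense ranks (1 = best); the default rule
intersects the per-measure top-m sets and orders by mean rank
(lexicographic tie-break); when the intersection is short the list is
completed by ascending mean rank. A union mode is provided since either
aggregation is defensible. Published absolute score cutoffs are
data-dependent and are deliberately not defaults; selection is rank-based.

MCODE: vertex weight = (highest k-core number of the closed neighborhood
graph) × (density of that k-core); seeds in descending weight; growth
admits unvisited neighbors with weight ≥ (1 − vwp) × seed weight
(vwp = 0.2); haircut drops singly-connected members; clusters lacking a
2-core are discarded; score = density × size. Fluff expansion is not
implemented.

## Enrichment

One-sided over-representation: with universe size N, set size M, query
size n and overlap k, `p = P(X ≥ k)` for X ~ Hypergeom(N, M, n)
(scipy's hypergeometric survival function; the test oracle recomputes it
in exact rational arithmetic). BH adjustment via statsmodels. The
significance flag defaults to the raw p at α = 0.05 (matching common
annotation-server practice) with the adjusted p always reported. The
combined score `−ln(p)·z` needs a caller-supplied z (the rank-permutation
background some services use is theirs, not reproducible here); without
z the field is absent, never 0.

## Drug prioritization

Receptors are ordered by ascending row mean of the affinity matrix and
drugs by ascending column mean (means rather than sums so that panels of
different sizes rank consistently; the orderings coincide on complete
matrices). Lead drugs must score strictly below the threshold (default
−7.0 kcal/mol) against **every** receptor; −7.0 exactly fails.
Cross-validation reports, per lead and independent panel, the fraction of
receptors bound below threshold, flagged at > 0.5. Lipinski evaluation
uses the four original rules (MW ≤ 500 Da, donors ≤ 5, acceptors ≤ 10,
logP ≤ 5), boundary values passing, with rotatable bonds recorded but not
counted; ≤ 1 violation keeps a molecule drug-like. Reactivity
descriptors: ΔE = E_LUMO − E_HOMO, I = −E_HOMO, A = −E_LUMO, η = (I−A)/2,
χ = (I+A)/2, μ = −χ, and σ = 1/η — the reciprocal-hardness reading of the
softness definition, the only one consistent with tabulated σ·η products;
σ is flagged undefined (NaN) at zero gap. ADMET quantities (HIA, BBB,
CYP, LC50 …) are pass-through annotations from external predictors, not
predicted here.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
on log2 scale throughout (linear-scale export exponentiates):

- per-gene baseline ~ N(8, 1) shared across diseases (one gene universe,
  ids `G000001…`), within-group noise N(0, noise_sd²);
- shared DEG blocks: +effect in cases in every disease (−effect for the
  down block); private DEG blocks shifted in one disease only,
  alternating direction;
- co-expression blocks from a latent factor,
  `x = √ρ f + √(1−ρ) ε` (scaled by noise_sd), giving expected pairwise
  correlation exactly ρ;
- PPI: Erdős–Rényi background at mean degree `background_degree` with
  hubs wired to `hub_degree` random partners;
- gene sets: planted sets containing the full target panel plus random
  fill, against uniform background sets;
- affinity: strong-binder columns at `strong_mean` (default −9) vs
  background (−5), Gaussian sd 0.3.

Defaults are the study conditions: 3 diseases, 2000 genes, 20+20 samples,
30 shared-up / 40 shared-down, 25 private DEGs per disease, effect 3.0,
noise 0.5, two co-expression blocks (60 and 45 genes, ρ = 0.8). With
effect/noise = 6 the fold-change standard error is ≈ 0.16, so planted
genes clear the ±1 threshold with margin; recovery failures would
indicate filter bugs, not sampling bad luck. What the generator does
*not* emulate: probe-level effects, batch effects, missing values,
heavy-tailed noise, correlated backgrounds between gene sets, and
affinity matrices with receptor-specific structure. Passing tests
therefore demonstrate correctness of the computations and sensible
behavior under the assumed model, not robustness to those real-data
complications.

## Calibration experiments

The one-sided Fisher exact test is conservative on coarse hypergeometric
supports, so a null-uniformity check must use configurations where the
attainable p-values are dense. The calibration uses a universe of 2000,
query 100, and set sizes {620, 890, 910, 1030, 1050}; for each, the exact
attainable rejection rate at α = 0.05 (computed from the hypergeometric
support, before simulation) is 0.0496–0.0500. The simulated rate over
2000 uniform-null replicates then falls in the nominal band. The BH FDR
experiment plants 20 strongly-overlapping signal sets among 80 null sets
and reports the mean false-discovery proportion at α = 0.05. The module
filter null uses 1000 pure-noise modules (30 genes × 40 samples).

## Problem sizes

Tests and the acceptance run use the default 2000-gene design (a few
seconds per disease for the TOM clustering), PPI panels of ~100 nodes
with 500 EPC iterations, and the calibration replicate counts above —
sizes chosen so the whole suite runs comfortably on a laptop while
keeping every statistical check well-powered.

## Known limitations

- The static TOM tree cut is a deliberate simplification of dynamic tree
  cutting; very unbalanced module structures may need a hand-tuned
  `cut_height`.
- EPC's percolation scheme is one concrete reading of an under-specified
  measure; scores are comparable within this package, not across tools.
- The enrichment z-score (and hence the combined score) is only as good
  as the caller-supplied background.
- Docking, DFT energies, ADMET prediction and MD simulation are upstream
  engines whose *outputs* this package consumes; none are reimplemented.
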