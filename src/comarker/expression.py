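"""Differential expression by average log2 fold-change with a co-expression
module filter.

The stage mirrors the common microarray meta-analysis workflow: per-gene
aLog2FC (difference of mean log2 expression between case and control
samples), an unsigned weighted co-expression network (|cor|^beta) whose
soft-threshold power is chosen by scale-free fit, topological-overlap (TOM)
clustering into modules, eigengene/trait correlation to keep only modules
that track the disease, and finally strict fold-change thresholds on the
retained genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

CASE = "case"
CONTROL = "control"
UNASSIGNED = "unassigned"


class ConfigurationError(ValueError):
    """A parameter violates its documented constraint."""


class DataError(ValueError):
    """Input data violates a contract (e.g. nonpositive linear-scale value)."""


@dataclass
class ExpressionStudy:
    """One disease's normalized genes x samples expression matrix.

    ``values`` is indexed by gene id with sample ids as columns;
    ``sample_groups`` maps each sample id to ``"case"`` or ``"control"``.
    ``scale`` declares whether entries are log2 expression or linear-scale
    responses (log2 is taken internally in the latter case).
    """

    disease_id: str
    values: pd.DataFrame
    sample_groups: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ConfigurationError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if not self.values.index.is_unique:
            raise DataError(f"{self.disease_id}: gene ids are not unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataError(f"{self.disease_id}: expression matrix contains non-finite values")
        groups = self.sample_groups.reindex(self.values.columns)
        if groups.isna().any():
            missing = list(self.values.columns[groups.isna()])
            raise DataError(f"{self.disease_id}: samples without group label: {missing}")
        bad = set(groups.unique()) - {CASE, CONTROL}
        if bad:
            raise DataError(f"{self.disease_id}: unknown group labels {sorted(bad)}")
        if (groups == CASE).sum() < 2 or (groups == CONTROL).sum() < 2:
            raise DataError(f"{self.disease_id}: need >= 2 case and >= 2 control samples")
        self.sample_groups = groups

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.sample_groups == CASE).to_numpy()

    def log2_matrix(self) -> pd.DataFrame:
        """Expression on log2 scale regardless of the stored scale."""
        if self.scale == "log2":
            return self.values
        vals = self.values.to_numpy()
        if (vals <= 0).any():
            g, s = np.argwhere(vals <= 0)[0]
            raise DataError(
                f"{self.disease_id}: nonpositive linear-scale value for gene "
                f"{self.values.index[g]!r} in sample {self.values.columns[s]!r}"
            )
        return pd.DataFrame(np.log2(vals), index=self.values.index, columns=self.values.columns)

    def trait_vector(self) -> np.ndarray:
        """0/1 per-sample disease indicator (1 = case), in column order."""
        return self.case_mask.astype(float)


@dataclass
class DEGTable:
    """Per-gene aLog2FC and direction calls (UR / DR / NS) for one disease."""

    disease_id: str
    table: pd.DataFrame  # index gene; columns: alog2fc, direction, module, module_trait_r

    @property
    def up_genes(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "UR"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "DR"])

    @property
    def alog2fc(self) -> pd.Series:
        return self.table["alog2fc"]


@dataclass
class SoftThresholdResult:
    beta: int
    r2_by_beta: dict[int, float]
    mean_connectivity: dict[int, float]
    warning: bool = False  # set when no candidate reached the cutoff


@dataclass
class ModuleResult:
    """Module assignment plus per-module eigengenes for one study."""

    beta: float
    module_assignment: pd.Series  # gene -> module label ("unassigned" allowed)
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns
    merge_heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    scale_free_r2: float | None = None
    module_trait: dict[str, tuple[float, float]] = field(default_factory=dict)

    def module_genes(self, label: str) -> list[str]:
        return list(self.module_assignment.index[self.module_assignment == label])

    @property
    def module_labels(self) -> list[str]:
        return [m for m in self.eigengenes.columns]


@dataclass
class ModuleFilterResult:
    retained_genes: frozenset[str]
    module_trait: dict[str, tuple[float, float]]  # module -> (r, p)
    significant_modules: list[str]


def compute_alog2fc(study: ExpressionStudy) -> pd.Series:
    """Average log2 fold-change per gene: mean(log2 case) - mean(log2 control).

    The paired equal-n and unpaired forms of the average log2 fold-change are
    algebraically identical (a mean of differences equals a difference of
    means), so a single difference-of-means branch serves both.
    """
    log2 = study.log2_matrix().to_numpy()
    case = study.case_mask
    fc = log2[:, case].mean(axis=1) - log2[:, ~case].mean(axis=1)
    return pd.Series(fc, index=study.values.index, name="alog2fc")


def _drop_constant_genes(log2: pd.DataFrame, context: str) -> pd.DataFrame:
    sd = log2.to_numpy().std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{context}: excluded {int((~keep).sum())} zero-variance gene(s) "
            "from the co-expression network",
            stacklevel=3,
        )
    return log2.loc[keep]


def _abs_correlation(log2: pd.DataFrame) -> np.ndarray:
    cor = np.corrcoef(log2.to_numpy())
    np.fill_diagonal(cor, 0.0)
    return np.abs(np.clip(cor, -1.0, 1.0))


def scale_free_fit_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10(frequency) vs log10(mean k) regression over k bins.

    High values indicate an approximately power-law (scale-free) degree /
    connectivity distribution.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_soft_threshold(
    study: ExpressionStudy,
    candidate_betas: list[int] | None = None,
    r2_cutoff: float = 0.84,
) -> SoftThresholdResult:
    """Choose the soft-threshold power for the unsigned co-expression network.

    Returns the smallest candidate beta whose scale-free fit reaches
    ``r2_cutoff``; if none does, the best-fitting beta is returned with a
    warning flag.
    """
    if candidate_betas is None:
        candidate_betas = list(range(1, 21))
    if not candidate_betas or any(int(b) != b or b < 1 for b in candidate_betas):
        raise ConfigurationError("candidate_betas must be positive integers")
    log2 = _drop_constant_genes(study.log2_matrix(), study.disease_id)
    acor = _abs_correlation(log2)
    r2_by_beta: dict[int, float] = {}
    mean_k: dict[int, float] = {}
    for beta in candidate_betas:
        k = np.power(acor, beta).sum(axis=1)
        r2_by_beta[int(beta)] = scale_free_fit_r2(k)
        mean_k[int(beta)] = float(k.mean())
    for beta in sorted(r2_by_beta):
        if r2_by_beta[beta] >= r2_cutoff:
            return SoftThresholdResult(beta, r2_by_beta, mean_k, warning=False)
    best = max(r2_by_beta, key=lambda b: (r2_by_beta[b], -b))
    return SoftThresholdResult(best, r2_by_beta, mean_k, warning=True)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of a (hollow) adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    TOM_ii = 1. Values lie in [0, 1] for adjacencies in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(log2_block: np.ndarray) -> np.ndarray:
    """Unit-norm first principal component (per sample) of a module.

    Rows are standardized genes; the sign is oriented so the eigengene
    correlates positively with the module's mean standardized profile.
    """
    x = np.asarray(log2_block, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    # right singular vector = per-sample component
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    profile = z.mean(axis=0)
    if np.dot(e, profile) < 0:
        e = -e
    n = np.linalg.norm(e)
    return e / n if n > 0 else e


def detect_modules(
    study: ExpressionStudy,
    beta: float,
    min_module_size: int = 30,
    merge_cut_height: float = 0.17,
    cut_height: float = 0.95,
) -> ModuleResult:
    """Cluster genes into co-expression modules via TOM dissimilarity.

    Average-linkage hierarchical clustering of 1 - TOM, a static cut at
    ``cut_height``, a minimum module size (smaller clusters are labelled
    "unassigned"), and iterative merging of modules whose eigengenes are
    closer than ``merge_cut_height`` in 1 - correlation.
    """
    if beta < 1:
        raise ConfigurationError("beta must be >= 1")
    if min_module_size < 2:
        raise ConfigurationError("min_module_size must be >= 2")
    log2_all = study.log2_matrix()
    log2 = _drop_constant_genes(log2_all, study.disease_id)
    genes = list(log2.index)
    samples = list(log2.columns)
    assignment = pd.Series(UNASSIGNED, index=log2_all.index, dtype=object)

    if len(genes) < min_module_size:
        warnings.warn(
            f"{study.disease_id}: only {len(genes)} usable genes "
            f"(< min_module_size={min_module_size}); all genes unassigned",
            stacklevel=2,
        )
        return ModuleResult(
            beta=beta,
            module_assignment=assignment,
            eigengenes=pd.DataFrame(index=samples),
        )

    acor = _abs_correlation(log2)
    adjacency = np.power(acor, beta)
    tom = topological_overlap(adjacency)
    dissim = 1.0 - tom
    z = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(gene)
    modules = [m for m in clusters.values() if len(m) >= min_module_size]

    # iterative eigengene merge
    x = log2.to_numpy()
    pos = {g: i for i, g in enumerate(genes)}
    while len(modules) > 1:
        eigs = np.array([_eigengene(x[[pos[g] for g in m]]) for m in modules])
        cor = np.corrcoef(eigs)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            break
        modules[i] = modules[i] + modules[j]
        del modules[j]

    modules.sort(key=lambda m: (-len(m), m[0]))
    eigengenes = {}
    for rank, members in enumerate(modules, start=1):
        label = f"M{rank}"
        assignment.loc[members] = label
        eigengenes[label] = _eigengene(x[[pos[g] for g in members]])
    eig_df = pd.DataFrame(eigengenes, index=samples)
    return ModuleResult(
        beta=beta,
        module_assignment=assignment,
        eigengenes=eig_df,
        merge_heights=z[:, 2].copy(),
    )


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t transform."""
    if n < 3:
        return 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


def filter_significant_modules(
    result: ModuleResult,
    trait: np.ndarray,
    r_threshold: float = 0.6,
    p_threshold: float = 0.001,
) -> ModuleFilterResult:
    """Retain genes of modules whose eigengene tracks the case/control trait.

    A module passes when |Pearson r(eigengene, trait)| >= r_threshold and the
    two-sided t-test p-value is < p_threshold.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != result.eigengenes.shape[0]:
        raise DataError("trait length must equal the sample count")
    if np.ptp(trait) == 0:
        raise DataError("trait has no variance")
    module_trait: dict[str, tuple[float, float]] = {}
    significant: list[str] = []
    for label in result.module_labels:
        e = result.eigengenes[label].to_numpy()
        if np.ptp(e) == 0:
            module_trait[label] = (float("nan"), 1.0)
            continue
        r = float(np.corrcoef(e, trait)[0, 1])
        p = correlation_pvalue(r, trait.shape[0])
        module_trait[label] = (r, p)
        if abs(r) >= r_threshold and p < p_threshold:
            significant.append(label)
    retained: set[str] = set()
    for label in significant:
        retained.update(result.module_genes(label))
    result.module_trait = module_trait
    return ModuleFilterResult(frozenset(retained), module_trait, significant)


def call_degs(
    alog2fc: pd.Series,
    retained_genes: frozenset[str] | set[str],
    disease_id: str = "",
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
    module_assignment: pd.Series | None = None,
    module_trait: dict[str, tuple[float, float]] | None = None,
) -> DEGTable:
    """Call UR/DR/NS per gene: strict fold-change thresholds, restricted to
    genes retained by the module filter."""
    if not down_threshold < up_threshold:
        raise ConfigurationError("down_threshold must be < up_threshold")
    retained = alog2fc.index.isin(retained_genes)
    direction = np.where(
        retained & (alog2fc.to_numpy() > up_threshold),
        "UR",
        np.where(retained & (alog2fc.to_numpy() < down_threshold), "DR", "NS"),
    )
    table = pd.DataFrame({"alog2fc": alog2fc, "direction": direction})
    if module_assignment is not None:
        table["module"] = module_assignment.reindex(alog2fc.index).fillna(UNASSIGNED)
        if module_trait is not None:
            table["module_trait_r"] = [
                module_trait.get(m, (np.nan, np.nan))[0] for m in table["module"]
            ]
    else:
        table["module"] = UNASSIGNED
        table["module_trait_r"] = np.nan
    return DEGTable(disease_id=disease_id, table=table)


@dataclass
class DEGStageParams:
    candidate_betas: list[int] | None = None
    r2_cutoff: float = 0.84
    min_module_size: int = 30
    merge_cut_height: float = 0.17
    cut_height: float = 0.95
    r_threshold: float = 0.6
    p_threshold: float = 0.001
    up_threshold: float = 1.0
    down_threshold: float = -1.0


def run_deg_stage(
    study: ExpressionStudy, params: DEGStageParams | None = None
) -> tuple[DEGTable, ModuleResult, ModuleFilterResult]:
    """Full per-disease stage: soft threshold, modules, trait filter, DEG calls."""
    params = params or DEGStageParams()
    soft = pick_soft_threshold(study, params.candidate_betas, params.r2_cutoff)
    modules = detect_modules(
        study,
        beta=soft.beta,
        min_module_size=params.min_module_size,
        merge_cut_height=params.merge_cut_height,
        cut_height=params.cut_height,
    )
    modules.scale_free_r2 = soft.r2_by_beta[soft.beta]
    filt = filter_significant_modules(
        modules, study.trait_vector(), params.r_threshold, params.p_threshold
    )
    fc = compute_alog2fc(study)
    table = call_degs(
        fc,
        filt.retained_genes,
        disease_id=study.disease_id,
        up_threshold=params.up_threshold,
        down_threshold=params.down_threshold,
        module_assignment=modules.module_assignment,
        module_trait=filt.module_trait,
    )
    return table, modules, filt
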