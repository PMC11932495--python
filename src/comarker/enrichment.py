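"""Gene-set over-representation analysis.

A query gene list is tested against each annotation set with the one-sided
Fisher exact test on the 2x2 table (query x set membership over a fixed
gene universe), i.e. the hypergeometric upper tail P(X >= k). Raw p-values
are Benjamini–Hochberg adjusted, and an Enrichr-style combined score
-ln(p) * z is reported when a caller-supplied z-score is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ConfigurationError, DataError


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe (GMT-compatible).

    ``sets`` maps a set id to ``(name, member genes)``; members outside the
    universe are dropped at construction (harmonization).
    """

    sets: dict[str, tuple[str, tuple[str, ...]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        harmonized = {}
        for sid, (name, members) in self.sets.items():
            kept = tuple(g for g in dict.fromkeys(members) if g in self.universe)
            if not kept:
                raise DataError(f"gene set {sid!r} is empty after harmonization")
            harmonized[sid] = (name, kept)
        self.sets = harmonized

    def __len__(self) -> int:
        return len(self.sets)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combined_score(p: float, z: float) -> float:
    """Enrichr-style combined score c = -ln(p) * z."""
    if not 0 < p <= 1:
        raise DataError(f"p must be in (0, 1], got {p}")
    return float(-np.log(p) * z)


def fisher_enrich(
    query,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    z_scores: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``query`` against every set.

    Returns a DataFrame sorted ascending by p with columns
    set_id, name, k, M, n, N, p, p_adj, significant and (when z-scores are
    supplied) combined. Significance is flagged on the raw p at ``alpha``;
    the BH-adjusted p is reported alongside. Query genes outside the
    universe are dropped with a warning.
    """
    query_set = set(query)
    dropped = query_set - collection.universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    query_set &= collection.universe
    if not query_set:
        raise DataError("query is empty after harmonization against the universe")
    n = len(query_set)
    n_universe = len(collection.universe)
    rows = []
    for sid, (name, members) in collection.sets.items():
        m = len(members)
        k = len(query_set.intersection(members))
        p = float(hypergeom.sf(k - 1, n_universe, m, n))
        rows.append((sid, name, k, m, n, n_universe, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_id", "name", "k", "M", "n", "N", "p"])
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p"] < alpha
    if z_scores is not None:
        out["combined"] = [
            combined_score(p, z_scores[sid]) if sid in z_scores else np.nan
            for sid, p in zip(out["set_id"], out["p"])
        ]
    out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return out
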