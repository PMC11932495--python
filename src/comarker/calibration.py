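"""Statistical calibration experiments for the enrichment test and the
module-trait filter.

These simulations check the two error-rate guarantees the pipeline leans
on: the one-sided Fisher exact test should reject at its nominal level
under a uniform null, and the module filter (|r| and p thresholds on the
eigengene-trait correlation) should almost never retain a pure-noise
module. The Fisher-null configuration uses large sets in a large universe
so the discrete hypergeometric support is fine enough for the p-value
distribution to be effectively uniform (the exact attainable rejection
rate at 0.05 is 0.0496-0.0500 for every set size used).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .expression import correlation_pvalue

# Universe / query / set sizes with near-continuous null p distributions.
NULL_UNIVERSE = 2000
NULL_QUERY = 100
NULL_SET_SIZES = (620, 890, 910, 1030, 1050)


def fisher_null_rejection_rate(
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    universe_size: int = NULL_UNIVERSE,
    query_size: int = NULL_QUERY,
    set_sizes: tuple[int, ...] = NULL_SET_SIZES,
) -> float:
    """Fraction of (replicate, set) Fisher tests with p < alpha when the
    query is drawn uniformly from the universe."""
    rng = np.random.default_rng(seed)
    # fixed sets; a uniformly drawn query makes overlap k hypergeometric
    rejections = 0
    total = 0
    for _ in range(n_replicates):
        query = rng.choice(universe_size, size=query_size, replace=False)
        marker = np.zeros(universe_size, dtype=bool)
        marker[query] = True
        for m in set_sizes:
            k = int(marker[:m].sum())  # set = first m genes, WLOG under uniformity
            p = hypergeom.sf(k - 1, universe_size, m, query_size)
            rejections += p < alpha
            total += 1
    return rejections / total


def bh_observed_fdr(
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_null_sets: int = 80,
    n_signal_sets: int = 20,
    universe_size: int = 2000,
    query_size: int = 100,
    set_size: int = 400,
    signal_overlap: int = 60,
) -> float:
    """Observed false-discovery proportion of BH at level alpha with planted
    signal sets (query strongly overlaps them) among null sets."""
    from .enrichment import bh_adjust

    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_replicates):
        ps = []
        truth = []
        for _ in range(n_signal_sets):
            # signal: overlap forced well above chance
            k = signal_overlap + rng.integers(-5, 6)
            ps.append(hypergeom.sf(k - 1, universe_size, set_size, query_size))
            truth.append(True)
        marker = np.zeros(universe_size, dtype=bool)
        marker[rng.choice(universe_size, size=query_size, replace=False)] = True
        for _ in range(n_null_sets):
            members = rng.choice(universe_size, size=set_size, replace=False)
            k = int(marker[members].sum())
            ps.append(hypergeom.sf(k - 1, universe_size, set_size, query_size))
            truth.append(False)
        adj = bh_adjust(ps)
        discovered = adj < alpha
        if discovered.sum():
            false = sum(d and not t for d, t in zip(discovered, truth))
            fdps.append(false / discovered.sum())
        else:
            fdps.append(0.0)
    return float(np.mean(fdps))


def null_module_retention_rate(
    n_replicates: int = 1000,
    n_samples: int = 40,
    n_genes: int = 30,
    r_threshold: float = 0.6,
    p_threshold: float = 0.001,
    seed: int = 0,
) -> float:
    """Fraction of pure-noise modules retained by the eigengene-trait filter.

    Each replicate builds a module of independent Gaussian genes, extracts
    its first principal component per sample, and applies the |r| >=
    r_threshold, p < p_threshold retention rule against a balanced 0/1
    trait.
    """
    rng = np.random.default_rng(seed)
    trait = np.zeros(n_samples)
    trait[: n_samples // 2] = 1.0
    retained = 0
    for _ in range(n_replicates):
        x = rng.normal(size=(n_genes, n_samples))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        r = float(np.corrcoef(e, trait)[0, 1])
        p = correlation_pvalue(r, n_samples)
        if abs(r) >= r_threshold and p < p_threshold:
            retained += 1
    return retained / n_replicates
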