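"""Cross-disease intersection of DEG calls and local genetic association.

Common DEGs (cDEGs) are genes called up-regulated in every disease or
down-regulated in every disease; the local genetic association between two
diseases is the Pearson correlation of their aLog2FC values over the cDEG
panel, with genes paired by id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DataError, DEGTable


@dataclass
class CDEGSet:
    """Direction-consistent common DEGs plus per-disease fold-changes.

    ``fold_changes`` is indexed by the sorted union of up and down genes,
    one column per disease — the shared ordering Pearson pairing requires.
    """

    up: list[str]
    down: list[str]
    fold_changes: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise DataError("up and down cDEG sets overlap")

    @property
    def genes(self) -> list[str]:
        return list(self.fold_changes.index)

    @property
    def diseases(self) -> list[str]:
        return list(self.fold_changes.columns)


def intersect_degs(tables: list[DEGTable]) -> CDEGSet:
    """Common DEGs: intersection of UR sets union intersection of DR sets."""
    if len(tables) < 2:
        raise DataError("need at least two DEG tables to intersect")
    universes = [set(t.table.index) for t in tables]
    shared_universe = set.intersection(*universes)
    if not shared_universe:
        raise DataError("DEG tables have disjoint gene universes")
    up = set.intersection(*[t.up_genes for t in tables])
    down = set.intersection(*[t.down_genes for t in tables])
    genes = sorted(up | down)
    fc = pd.DataFrame(
        {t.disease_id: t.alog2fc.reindex(genes) for t in tables}, index=genes
    )
    return CDEGSet(up=sorted(up), down=sorted(down), fold_changes=fc)


def local_association(cdegs: CDEGSet) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-disease aLog2FC over all cDEGs.

    Returns a symmetric diseases x diseases matrix with unit diagonal.
    Zero-variance fold-change vectors yield NaN entries with a warning
    rather than a silent 0.
    """
    if len(cdegs.genes) < 3:
        raise DataError("need at least 3 cDEGs for a meaningful correlation")
    x = cdegs.fold_changes.to_numpy(dtype=float)
    sd = x.std(axis=0)
    degenerate = [d for d, s in zip(cdegs.diseases, sd) if s == 0]
    if degenerate:
        warnings.warn(
            f"zero-variance aLog2FC vector(s) for {degenerate}; "
            "correlations involving them are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    for i, d in enumerate(cdegs.diseases):
        if sd[i] == 0:
            r[i, :] = np.nan
            r[:, i] = np.nan
            r[i, i] = 1.0
    return pd.DataFrame(r, index=cdegs.diseases, columns=cdegs.diseases)
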