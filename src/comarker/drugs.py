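"""Docking-score-matrix drug prioritization, Lipinski drug-likeness, and
frontier-molecular-orbital reactivity descriptors.

Binding-affinity scores are in kcal/mol with more negative meaning stronger
predicted binding; receptors are ranked by row mean and drugs by column
mean, lead drugs must bind below a threshold against *every* receptor, and
leads are cross-checked against independent receptor panels. Conceptual-DFT
descriptors (gap, hardness, softness, electronegativity, chemical
potential) are derived from HOMO/LUMO energies in Hartree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ConfigurationError, DataError


@dataclass
class AffinityMatrix:
    """Receptors x drugs binding-affinity scores (kcal/mol, negative)."""

    scores: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scores.empty:
            raise DataError("affinity matrix is empty")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise DataError("affinity matrix contains non-finite entries")

    @property
    def receptors(self) -> list[str]:
        return list(self.scores.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.scores.columns)


def rank_receptors_and_drugs(
    matrix: AffinityMatrix,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Order receptors by ascending row mean and drugs by ascending column
    mean (most negative = strongest binding first); ties break by id. The
    reordered matrix is returned for heatmap export."""
    row_mean = matrix.scores.mean(axis=1)
    col_mean = matrix.scores.mean(axis=0)
    receptor_order = sorted(matrix.receptors, key=lambda r: (row_mean[r], str(r)))
    drug_order = sorted(matrix.drugs, key=lambda d: (col_mean[d], str(d)))
    return receptor_order, drug_order, matrix.scores.loc[receptor_order, drug_order]


def select_lead_drugs(matrix: AffinityMatrix, threshold: float = -7.0) -> list[str]:
    """Drugs scoring strictly below ``threshold`` against every receptor,
    ordered by ascending column mean."""
    if threshold >= 0:
        raise ConfigurationError("threshold must be negative (kcal/mol)")
    passing = (matrix.scores < threshold).all(axis=0)
    col_mean = matrix.scores.mean(axis=0)
    leads = [d for d in matrix.drugs if passing[d]]
    return sorted(leads, key=lambda d: (col_mean[d], str(d)))


def cross_validate_leads(
    lead_drugs: list[str],
    validation_matrices: list[AffinityMatrix],
    threshold: float = -7.0,
    most_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per lead drug and validation panel, the fraction of independent
    receptors bound below ``threshold``, with a "binds most receptors" flag
    at fraction > ``most_fraction``."""
    rows = []
    for panel_idx, matrix in enumerate(validation_matrices):
        missing = [d for d in lead_drugs if d not in matrix.scores.columns]
        if missing:
            raise DataError(f"validation panel {panel_idx}: missing drug column(s) {missing}")
        label = matrix.provenance or f"panel{panel_idx + 1}"
        for drug in lead_drugs:
            frac = float((matrix.scores[drug] < threshold).mean())
            rows.append((drug, label, frac, frac > most_fraction))
    return pd.DataFrame(rows, columns=["drug", "panel", "pass_fraction", "binds_most"])


@dataclass
class MolecularProperties:
    """Physicochemical properties used by the Lipinski screen."""

    drug_id: str
    mol_weight: float  # Da
    h_bond_donors: int
    h_bond_acceptors: int
    logp: float
    rotatable_bonds: int | None = None  # recorded, not a Lipinski rule

    def __post_init__(self) -> None:
        for name in ("mol_weight", "h_bond_donors", "h_bond_acceptors"):
            value = getattr(self, name)
            if value is None or value < 0:
                raise DataError(f"{self.drug_id}: {name} must be nonnegative, got {value}")
        if self.logp is None:
            raise DataError(f"{self.drug_id}: logp is missing")


@dataclass
class LipinskiResult:
    drug_id: str
    flags: dict[str, bool]  # True = rule satisfied
    violations: int
    drug_like: bool  # <= 1 violation tolerated


def lipinski_evaluate(props: MolecularProperties) -> LipinskiResult:
    """Lipinski rule of five: MW <= 500 Da, H-bond donors <= 5, H-bond
    acceptors <= 10, logP <= 5. Boundary values pass; a molecule remains
    drug-like with at most one violation."""
    flags = {
        "mol_weight": props.mol_weight <= 500,
        "h_bond_donors": props.h_bond_donors <= 5,
        "h_bond_acceptors": props.h_bond_acceptors <= 10,
        "logp": props.logp <= 5,
    }
    violations = sum(not ok for ok in flags.values())
    return LipinskiResult(
        drug_id=props.drug_id, flags=flags, violations=violations, drug_like=violations <= 1
    )


@dataclass
class OrbitalEnergies:
    """Frontier molecular orbital energies in Hartree."""

    drug_id: str
    e_homo: float
    e_lumo: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_homo) and np.isfinite(self.e_lumo)):
            raise DataError(f"{self.drug_id}: orbital energies must be finite")
        if self.e_homo >= self.e_lumo:
            warnings.warn(
                f"{self.drug_id}: E_HOMO >= E_LUMO (unexpected for a closed-shell "
                "ground state)",
                stacklevel=2,
            )


@dataclass
class ReactivityDescriptors:
    """Conceptual-DFT descriptors; Hartree throughout except softness
    (Hartree^-1)."""

    drug_id: str
    gap: float  # ΔE = E_LUMO - E_HOMO
    ionization_potential: float  # I = -E_HOMO
    electron_affinity: float  # A = -E_LUMO
    hardness: float  # η = (I - A) / 2
    softness: float  # σ = 1/η (NaN when η = 0)
    electronegativity: float  # χ = (I + A) / 2
    chemical_potential: float  # μ = -χ
    softness_defined: bool = True


def reactivity_descriptors(orbitals: OrbitalEnergies) -> ReactivityDescriptors:
    """Derive the reactivity descriptor set from HOMO/LUMO energies.

    Softness is the reciprocal hardness; for a zero gap it is undefined and
    flagged rather than reported as infinity.
    """
    ip = -orbitals.e_homo
    ea = -orbitals.e_lumo
    gap = orbitals.e_lumo - orbitals.e_homo
    hardness = (ip - ea) / 2.0
    chi = (ip + ea) / 2.0
    if hardness == 0:
        softness, defined = float("nan"), False
        warnings.warn(f"{orbitals.drug_id}: zero hardness, softness undefined", stacklevel=2)
    else:
        softness, defined = 1.0 / hardness, True
    return ReactivityDescriptors(
        drug_id=orbitals.drug_id,
        gap=gap,
        ionization_potential=ip,
        electron_affinity=ea,
        hardness=hardness,
        softness=softness,
        electronegativity=chi,
        chemical_potential=-chi,
        softness_defined=defined,
    )


def reactivity_table(orbital_rows: list[OrbitalEnergies]) -> pd.DataFrame:
    """Descriptor table (one row per drug) for CSV export."""
    rows = []
    for orb in orbital_rows:
        d = reactivity_descriptors(orb)
        rows.append(
            {
                "drug": d.drug_id,
                "e_homo": orb.e_homo,
                "e_lumo": orb.e_lumo,
                "gap": d.gap,
                "ionization_potential": d.ionization_potential,
                "electron_affinity": d.electron_affinity,
                "hardness": d.hardness,
                "softness": d.softness,
                "electronegativity": d.electronegativity,
                "chemical_potential": d.chemical_potential,
            }
        )
    return pd.DataFrame(rows).set_index("drug")
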