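"""Unit conversions between assay and molar concentration scales.

Bevacizumab is assayed in mg/L and free VEGF-A in ng/L, but the binding
model works in nM so that drug and ligand can be balanced mole-for-mole
(1:1 stoichiometry). Molecular weights: bevacizumab 149 kDa, VEGF-A 45 kDa.
"""

from __future__ import annotations

from dataclasses import dataclass

#: drug observable label (bevacizumab, assayed in mg/L)
DRUG = "drug"
#: ligand observable label (free VEGF-A, assayed in ng/L)
LIGAND = "ligand"


@dataclass(frozen=True)
class MolarConstants:
    """Molecular weights (kDa) and binding stoichiometry of the drug-ligand pair."""

    mw_drug_kda: float = 149.0
    mw_ligand_kda: float = 45.0
    stoichiometry: int = 1

    def __post_init__(self) -> None:
        if self.mw_drug_kda <= 0 or self.mw_ligand_kda <= 0:
            raise ValueError("molecular weights must be positive")


DEFAULT_CONSTANTS = MolarConstants()


def to_molar(value: float, analyte: str, constants: MolarConstants = DEFAULT_CONSTANTS) -> float:
    """Convert an assay-scale concentration to nM.

    drug: mg/L -> nM via nM = mg/L * 1e6 / (kDa * 1000)
    ligand: ng/L -> nM via nM = ng/L / (kDa * 1000)   (kDa*1000 = ng/nmol ... g/mol)
    """
    if analyte == DRUG:
        return value * 1e6 / (constants.mw_drug_kda * 1000.0)
    if analyte == LIGAND:
        return value / (constants.mw_ligand_kda * 1000.0)
    raise ValueError(f"unknown analyte {analyte!r}; expected 'drug' or 'ligand'")


def from_molar(value_nm: float, analyte: str, constants: MolarConstants = DEFAULT_CONSTANTS) -> float:
    """Convert nM back to the assay scale (mg/L for drug, ng/L for ligand)."""
    if analyte == DRUG:
        return value_nm * (constants.mw_drug_kda * 1000.0) / 1e6
    if analyte == LIGAND:
        return value_nm * (constants.mw_ligand_kda * 1000.0)
    raise ValueError(f"unknown analyte {analyte!r}; expected 'drug' or 'ligand'")


def drug_mg_per_l_to_nm(x):
    """Vector-friendly drug mg/L -> nM with default molecular weight."""
    return x * (1e6 / 149000.0)


def drug_mg_to_nmol(x):
    """Dose amount mg -> nmol of drug."""
    return x * (1e6 / 149000.0)


def drug_nm_to_mg_per_l(x):
    return x * (149000.0 / 1e6)


def ligand_nm_to_ng_per_l(x):
    return x * 45000.0


def ligand_ng_per_l_to_nm(x):
    return x / 45000.0
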