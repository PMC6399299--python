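"""Drug-like library construction and docking-score post-processing.

Implements the library filters (Lipinski rule counting with a 170–1000 Da
molecular-weight window, structure-key deduplication), the Boltzmann
conversion of a docking score ΔG (kcal/mol) to an inhibition constant
Ki = exp(ΔG/RT) with R = 1.9872036e-3 kcal K⁻¹ mol⁻¹ and T = 300 K, the
-6 kcal/mol docking confidence filter, and target-family enrichment of
screen hits.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .pocket_similarity import ScreenHit

__all__ = [
    "CompoundRecord",
    "DockingRecord",
    "GAS_CONSTANT_KCAL",
    "DOCKING_TEMPERATURE_K",
    "DOCKING_CONFIDENCE_CUTOFF",
    "MW_WINDOW",
    "lipinski_violations",
    "druglike_filter",
    "dedupe_by_key",
    "ki_from_docking",
    "docking_confidence_filter",
    "target_enrichment",
    "read_compound_table",
    "compound_table_to_df",
]

#: Gas constant in kcal K^-1 mol^-1 and the assumed docking temperature.
GAS_CONSTANT_KCAL = 1.9872036e-3
DOCKING_TEMPERATURE_K = 300.0
#: High-confidence binders have docking ΔG strictly below this (kcal/mol).
DOCKING_CONFIDENCE_CUTOFF = -6.0
#: Drug-like molecular weight window in Da (inclusive).
MW_WINDOW = (170.0, 1000.0)


@dataclass
class CompoundRecord:
    """One library ligand with its drug-likeness descriptors.

    Hydrogen-bond acceptors are supplied as N+O counts; logP is a supplied
    number, never computed here.
    """

    ligand_id: str
    mw: float
    logp: float
    hbd: int
    hba: int
    structure_key: str = ""
    smiles: Optional[str] = None
    target_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"{self.ligand_id}: molecular weight must be positive")


@dataclass
class DockingRecord:
    """A ligand's docking score and the Ki derived from it."""

    ligand_id: str
    delta_g: float
    ki: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ki is None:
            self.ki = ki_from_docking(self.delta_g)


def lipinski_violations(rec: CompoundRecord) -> int:
    """Count of Lipinski rule violations (0–4).

    Rules: MW > 500 Da, logP > 5, H-bond donors > 5, H-bond acceptors > 10.
    """
    for field_name in ("mw", "logp", "hbd", "hba"):
        value = getattr(rec, field_name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"{rec.ligand_id}: missing descriptor {field_name!r}")
    return sum([rec.mw > 500, rec.logp > 5, rec.hbd > 5, rec.hba > 10])


def druglike_filter(table: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Keep compounds with fewer than 2 Lipinski violations and MW within
    the 170–1000 Da window (inclusive bounds)."""
    lo, hi = MW_WINDOW
    return [
        rec for rec in table if lipinski_violations(rec) < 2 and lo <= rec.mw <= hi
    ]


def dedupe_by_key(table: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """One record per structure key (InChIKey or equivalent), keeping the
    first occurrence in input order."""
    seen: set[str] = set()
    out = []
    for rec in table:
        if not rec.structure_key:
            raise ValueError(f"{rec.ligand_id}: empty structure key")
        if rec.structure_key not in seen:
            seen.add(rec.structure_key)
            out.append(rec)
    return out


def ki_from_docking(
    delta_g: float,
    R: float = GAS_CONSTANT_KCAL,
    T: float = DOCKING_TEMPERATURE_K,
) -> float:
    """Ki (molar) from a docking score: Ki = exp(ΔG / (R·T)).

    Strictly increasing in ΔG; ΔG = 0 gives 1 M.
    """
    if not math.isfinite(delta_g):
        raise ValueError(f"docking score must be finite, got {delta_g!r}")
    if R <= 0 or T <= 0:
        raise ValueError("R and T must be positive")
    return math.exp(delta_g / (R * T))


def docking_confidence_filter(
    records: Iterable[DockingRecord],
    cutoff: float = DOCKING_CONFIDENCE_CUTOFF,
) -> list[DockingRecord]:
    """Keep high-confidence binders: ΔG strictly below the cutoff."""
    return [rec for rec in records if rec.delta_g < cutoff]


def target_enrichment(hits: Iterable[ScreenHit]) -> pd.DataFrame:
    """Per-target-family hit counts, descending, ties broken alphabetically.

    Unannotated hits are pooled under the family ``"other"``.
    """
    counts = Counter((h.target_family or "other") for h in hits)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["target_family", "ligand_count"])


# ---------------------------------------------------------------------------
# tabular I/O


def read_compound_table(path, sep: str = "\t") -> list[CompoundRecord]:
    """Read a compound table (TSV/CSV with header: ligand_id, smiles, mw,
    logp, hbd, hba, structure_key, target_family)."""
    df = pd.read_csv(path, sep=sep)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                ligand_id=str(row.ligand_id),
                smiles=getattr(row, "smiles", None),
                mw=float(row.mw),
                logp=float(row.logp),
                hbd=int(row.hbd),
                hba=int(row.hba),
                structure_key=str(getattr(row, "structure_key", "") or ""),
                target_family=getattr(row, "target_family", None),
            )
        )
    return records


def compound_table_to_df(table: Sequence[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "smiles": r.smiles,
                "mw": r.mw,
                "logp": r.logp,
                "hbd": r.hbd,
                "hba": r.hba,
                "structure_key": r.structure_key,
                "target_family": r.target_family,
            }
            for r in table
        ]
    )
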