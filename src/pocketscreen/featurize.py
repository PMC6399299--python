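"""Residue microenvironment featurization.

Each pocket residue is described by the protein (and non-cognate hetero)
heavy atoms surrounding its side-chain centroid, partitioned into six
concentric 1 Å shells. Every shell contributes 80 physicochemical count
descriptors, giving a 480-length vector per residue; vectors are binarized
(presence/absence) for Tanimoto comparison. The layout is shell-major:
positions 0–79 are shell 1 (0 < d ≤ 1 Å), 80–159 shell 2, and so on.

The 80 descriptors per shell (``default-v1`` schema):

====================================  =====
category                              count
====================================  =====
element counts C/N/O/S/P/other            6
per-residue-type atom counts             20
residue-class atom counts                 6
backbone / side-chain atom counts         2
H-bond donor / acceptor heavy atoms       2
positive / negative charged-group atoms   2
aromatic-ring atoms                       1
total heavy atoms                         1
hydropathy |KD| sums in 5 signed bins     5
element × residue-class cross counts     35
====================================  =====
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure_io import (
    AtomRecord,
    LigandInstance,
    PocketDefinition,
    ResidueRecord,
    StructureModel,
)

__all__ = [
    "PropertySchema",
    "Microenvironment",
    "PocketFeatureSet",
    "SchemaMismatchError",
    "default_schema",
    "residue_center",
    "featurize_microenvironment",
    "binarize",
    "featurize_pocket",
]

STANDARD_AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# Physicochemical residue classes (each standard residue in exactly one).
RESIDUE_CLASSES: dict[str, tuple[str, ...]] = {
    "hydrophobic": ("ALA", "VAL", "LEU", "ILE", "MET"),
    "aromatic": ("PHE", "TRP", "TYR"),
    "polar": ("SER", "THR", "ASN", "GLN"),
    "positive": ("ARG", "LYS", "HIS"),
    "negative": ("ASP", "GLU"),
    "special": ("GLY", "PRO", "CYS"),
}
CLASS_NAMES = tuple(RESIDUE_CLASSES) + ("other",)  # "other" = non-standard residues
_RES_TO_CLASS = {res: cls for cls, members in RESIDUE_CLASSES.items() for res in members}

# Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9, "TYR": -1.3,
    "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5, "ASP": -3.5, "ASN": -3.5,
    "LYS": -3.9, "ARG": -4.5,
}
# Signed hydropathy bins: strongly/mildly hydrophilic, neutral, mildly/strongly hydrophobic.
KD_BIN_EDGES = (-2.7, -0.9, 0.9, 2.7)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Heavy atoms that can donate / accept hydrogen bonds (side chain + backbone).
_DONOR_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
}
_ACCEPTOR_ATOMS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "MET": frozenset({"SD"}),
}
_POSITIVE_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "CZ", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}
_NEGATIVE_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"CG", "OD1", "OD2"}),
    "GLU": frozenset({"CD", "OE1", "OE2"}),
}
_AROMATIC_RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}

_ELEMENTS = ("C", "N", "O", "S", "P")


class SchemaMismatchError(ValueError):
    """Raised when feature vectors from different schemas are compared."""


def _descriptor_names() -> list[str]:
    names = [f"elem_{e}" for e in _ELEMENTS] + ["elem_other"]
    names += [f"restype_{res}" for res in STANDARD_AMINO_ACIDS]
    names += [f"class_{cls}" for cls in RESIDUE_CLASSES]
    names += ["backbone_atoms", "sidechain_atoms"]
    names += ["hbond_donor", "hbond_acceptor"]
    names += ["positive_charge_atoms", "negative_charge_atoms"]
    names += ["aromatic_ring_atoms"]
    names += ["total_heavy_atoms"]
    names += [f"kd_bin_{i}" for i in range(1, 6)]
    names += [f"cross_{e}_{cls}" for e in _ELEMENTS for cls in CLASS_NAMES]
    return names


@dataclass(frozen=True)
class PropertySchema:
    """Versioned definition of the per-shell descriptor set.

    Feature vectors are only comparable when produced by the same schema;
    every :class:`Microenvironment` carries the ``schema_id`` that made it.
    """

    schema_id: str
    descriptors: tuple[str, ...]
    shell_count: int = 6
    shell_width: float = 1.0
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("descriptor names must be unique")
        if self.thresholds and len(self.thresholds) != self.total_length:
            raise ValueError("thresholds must match total vector length")

    @property
    def per_shell(self) -> int:
        return len(self.descriptors)

    @property
    def total_length(self) -> int:
        return self.shell_count * self.per_shell

    @property
    def radius(self) -> float:
        return self.shell_count * self.shell_width

    def threshold_array(self) -> np.ndarray:
        if self.thresholds:
            return np.asarray(self.thresholds, dtype=float)
        return np.zeros(self.total_length)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_id": self.schema_id,
                "shell_count": self.shell_count,
                "shell_width": self.shell_width,
                "descriptors": list(self.descriptors),
            },
            indent=2,
        )


_DEFAULT_SCHEMA: Optional[PropertySchema] = None


def default_schema() -> PropertySchema:
    """The shipped ``default-v1`` schema: 6 shells × 80 count descriptors."""
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        names = _descriptor_names()
        assert len(names) == 80
        _DEFAULT_SCHEMA = PropertySchema(schema_id="default-v1", descriptors=tuple(names))
    return _DEFAULT_SCHEMA


@dataclass
class Microenvironment:
    """The featurized 6 Å neighborhood of one pocket residue."""

    residue_ref: tuple[str, int, str]
    center: np.ndarray
    values: np.ndarray
    bits: np.ndarray
    schema_id: str


@dataclass
class PocketFeatureSet:
    """Ordered microenvironments of one pocket, plus screening metadata."""

    pocket_id: str
    microenvironments: list[Microenvironment]
    schema_id: str
    cognate_ligand: Optional[str] = None
    target_family: Optional[str] = None

    def __len__(self) -> int:
        return len(self.microenvironments)

    def bit_matrix(self) -> np.ndarray:
        return np.array([m.bits for m in self.microenvironments], dtype=np.uint8)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pocket_id": self.pocket_id,
                "schema_id": self.schema_id,
                "cognate_ligand": self.cognate_ligand,
                "target_family": self.target_family,
                "microenvironments": [
                    {
                        "residue_ref": list(m.residue_ref),
                        "center": [float(x) for x in m.center],
                        "values": [float(v) for v in m.values],
                    }
                    for m in self.microenvironments
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str, schema: Optional[PropertySchema] = None) -> "PocketFeatureSet":
        payload = json.loads(text)
        schema = schema or default_schema()
        if payload["schema_id"] != schema.schema_id:
            raise SchemaMismatchError(
                f"feature set was built with schema {payload['schema_id']!r}, "
                f"expected {schema.schema_id!r}"
            )
        mes = []
        for m in payload["microenvironments"]:
            values = np.asarray(m["values"], dtype=float)
            mes.append(
                Microenvironment(
                    residue_ref=tuple(m["residue_ref"]),
                    center=np.asarray(m["center"], dtype=float),
                    values=values,
                    bits=binarize(values, schema),
                    schema_id=payload["schema_id"],
                )
            )
        return cls(
            pocket_id=payload["pocket_id"],
            microenvironments=mes,
            schema_id=payload["schema_id"],
            cognate_ligand=payload.get("cognate_ligand"),
            target_family=payload.get("target_family"),
        )


# ---------------------------------------------------------------------------
# featurization


def residue_center(residue: ResidueRecord) -> np.ndarray:
    """Geometric center of the residue's side-chain heavy atoms.

    Glycine (or a residue with no resolved side chain) falls back to the CA
    position; a residue lacking CA falls back to the all-heavy-atom centroid.
    """
    heavy = residue.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.key} has no heavy atoms")
    side = [a for a in heavy if a.name not in BACKBONE_ATOMS]
    if side:
        return np.mean([a.coords for a in side], axis=0)
    for atom in heavy:
        if atom.name == "CA":
            return np.asarray(atom.coords, dtype=float)
    return np.mean([a.coords for a in heavy], axis=0)


def _annotate(atom: AtomRecord, res_type: str, is_polymer: bool) -> dict:
    elem = atom.element.upper()
    cls = _RES_TO_CLASS.get(res_type, "other") if is_polymer else "other"
    backbone = is_polymer and atom.name in BACKBONE_ATOMS
    donor = is_polymer and (
        (atom.name == "N" and res_type != "PRO")
        or atom.name in _DONOR_ATOMS.get(res_type, ())
    )
    acceptor = is_polymer and (
        atom.name in ("O", "OXT") or atom.name in _ACCEPTOR_ATOMS.get(res_type, ())
    )
    return {
        "element": elem,
        "res_type": res_type,
        "res_class": cls,
        "backbone": backbone,
        "donor": donor,
        "acceptor": acceptor,
        "positive": is_polymer and atom.name in _POSITIVE_ATOMS.get(res_type, ()),
        "negative": is_polymer
        and (atom.name in _NEGATIVE_ATOMS.get(res_type, ()) or atom.name == "OXT"),
        "aromatic": is_polymer and atom.name in _AROMATIC_RING_ATOMS.get(res_type, ()),
        "kd": KYTE_DOOLITTLE.get(res_type, 0.0) if is_polymer else 0.0,
    }


def _model_heavy_atoms(
    model: StructureModel, exclude_ligand: Optional[LigandInstance]
) -> tuple[np.ndarray, list[dict]]:
    coords: list[tuple[float, float, float]] = []
    annots: list[dict] = []
    for res in model.residues:
        for atom in res.atoms:
            if atom.is_heavy:
                coords.append(atom.coords)
                annots.append(_annotate(atom, res.res_type, is_polymer=True))
    for lig in model.ligands:
        if exclude_ligand is not None and (
            lig.het_code == exclude_ligand.het_code
            and lig.chain == exclude_ligand.chain
            and lig.seq_number == exclude_ligand.seq_number
        ):
            continue
        for atom in lig.atoms:
            if atom.is_heavy:
                coords.append(atom.coords)
                annots.append(_annotate(atom, lig.het_code, is_polymer=False))
    if not coords:
        return np.empty((0, 3)), []
    return np.asarray(coords, dtype=float), annots


def _shell_vector(shell_atoms: Sequence[dict], schema: PropertySchema) -> np.ndarray:
    vec = np.zeros(schema.per_shell)
    idx = {name: i for i, name in enumerate(schema.descriptors)}
    for a in shell_atoms:
        elem = a["element"] if a["element"] in _ELEMENTS else None
        vec[idx[f"elem_{elem}"] if elem else idx["elem_other"]] += 1
        if a["res_type"] in STANDARD_AMINO_ACIDS:
            vec[idx[f"restype_{a['res_type']}"]] += 1
        if a["res_class"] != "other":
            vec[idx[f"class_{a['res_class']}"]] += 1
        vec[idx["backbone_atoms" if a["backbone"] else "sidechain_atoms"]] += 1
        if a["donor"]:
            vec[idx["hbond_donor"]] += 1
        if a["acceptor"]:
            vec[idx["hbond_acceptor"]] += 1
        if a["positive"]:
            vec[idx["positive_charge_atoms"]] += 1
        if a["negative"]:
            vec[idx["negative_charge_atoms"]] += 1
        if a["aromatic"]:
            vec[idx["aromatic_ring_atoms"]] += 1
        vec[idx["total_heavy_atoms"]] += 1
        kd = a["kd"]
        if a["res_type"] in KYTE_DOOLITTLE:
            b = int(np.searchsorted(KD_BIN_EDGES, kd, side="right"))
            vec[idx[f"kd_bin_{b + 1}"]] += abs(kd)
        if elem:
            vec[idx[f"cross_{elem}_{a['res_class']}"]] += 1
    return vec


def featurize_microenvironment(
    model: StructureModel,
    center: np.ndarray,
    schema: Optional[PropertySchema] = None,
    exclude_ligand: Optional[LigandInstance] = None,
    residue_ref: tuple[str, int, str] = ("", 0, ""),
) -> Microenvironment:
    """Featurize the neighborhood of ``center``.

    Every heavy atom of the model except those of ``exclude_ligand`` (the
    pocket's own co-crystal ligand, so pockets stay comparable across bound
    ligands) is assigned to exactly one shell by its distance ``d`` from the
    center: shell ``k`` covers ``(k-1)·w < d ≤ k·w``. Atoms beyond the last
    shell — and an atom exactly at the center — contribute nothing.
    """
    schema = schema or default_schema()
    center = np.asarray(center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    coords, annots = _model_heavy_atoms(model, exclude_ligand)
    if coords.shape[0]:
        d = np.linalg.norm(coords - center[None, :], axis=1)
    else:
        d = np.empty(0)
    shells: list[list[dict]] = [[] for _ in range(schema.shell_count)]
    w = schema.shell_width
    for dist, annot in zip(d, annots):
        if dist <= 0 or dist > schema.radius:
            continue
        k = int(np.ceil(dist / w)) - 1
        k = min(k, schema.shell_count - 1)
        shells[k].append(annot)
    values = np.concatenate([_shell_vector(s, schema) for s in shells])
    return Microenvironment(
        residue_ref=residue_ref,
        center=center,
        values=values,
        bits=binarize(values, schema),
        schema_id=schema.schema_id,
    )


def binarize(values: np.ndarray, schema: Optional[PropertySchema] = None) -> np.ndarray:
    """Presence/absence bits: 1 where a value exceeds its descriptor threshold
    (0 for all count descriptors in the default schema)."""
    schema = schema or default_schema()
    values = np.asarray(values, dtype=float)
    if values.shape != (schema.total_length,):
        raise ValueError(
            f"vector length {values.shape} does not match schema length {schema.total_length}"
        )
    return (values > schema.threshold_array()).astype(np.uint8)


def featurize_pocket(
    model: StructureModel,
    pocket: PocketDefinition,
    schema: Optional[PropertySchema] = None,
    exclude_ligand: Optional[LigandInstance] = None,
    target_family: Optional[str] = None,
) -> PocketFeatureSet:
    """Featurize every pocket residue, preserving pocket order."""
    schema = schema or default_schema()
    mes = []
    for res in pocket.residues(model):
        try:
            center = residue_center(res)
            me = featurize_microenvironment(
                model, center, schema, exclude_ligand=exclude_ligand, residue_ref=res.key
            )
        except ValueError as exc:
            raise ValueError(f"residue {res.key}: {exc}") from exc
        mes.append(me)
    return PocketFeatureSet(
        pocket_id=pocket.pocket_id,
        microenvironments=mes,
        schema_id=schema.schema_id,
        cognate_ligand=pocket.ligand_ref,
        target_family=target_family,
    )
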