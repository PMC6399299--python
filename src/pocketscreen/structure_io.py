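"""Coordinate-file parsing and ligand-binding-pocket extraction.

A drug-binding pocket is defined geometrically: every polymer residue with
at least one heavy atom within a distance cutoff (default 6.0 Å, inclusive)
of any heavy atom of a bound small molecule. Parsing is delegated to gemmi
(PDB and mmCIF); this module flattens the first coordinate model into plain
dataclasses that the featurization and scoring layers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "LigandInstance",
    "StructureModel",
    "PocketDefinition",
    "StructureParseError",
    "EmptyModelError",
    "InvalidLigandError",
    "DEFAULT_EXCLUDED_HET_CODES",
    "parse_structure",
    "list_ligand_instances",
    "extract_pocket",
    "write_pdb",
    "pocket_to_json",
    "pocket_to_tsv",
]

#: Het codes never treated as screening ligands nor as pocket members:
#: water, common ions, and frequent crystallization additives.
DEFAULT_EXCLUDED_HET_CODES = frozenset(
    {"HOH", "DOD", "WAT", "NA", "K", "CL", "MG", "ZN", "CA", "GOL", "EDO", "SO4", "PO4"}
)

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyModelError(StructureParseError):
    """Raised when a parsed structure contains no residues at all."""


class InvalidLigandError(ValueError):
    """Raised when a ligand has no heavy atoms to measure distances from."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: label, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name!r} has an empty element symbol")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass
class ResidueRecord:
    """One polymer residue of the model."""

    chain: str
    seq_number: int
    res_type: str
    atoms: list[AtomRecord]
    insertion_code: str = ""
    is_polymer: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_number, self.insertion_code)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class LigandInstance:
    """A hetero group (candidate co-crystal ligand) with its locator."""

    het_code: str
    chain: str
    seq_number: int
    atoms: list[AtomRecord]
    insertion_code: str = ""

    @property
    def locator(self) -> str:
        return f"{self.chain}:{self.seq_number}{self.insertion_code}"

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class StructureModel:
    """The first coordinate model of an entry: polymer residues + hetero groups."""

    structure_id: str
    residues: list[ResidueRecord]
    ligands: list[LigandInstance]
    model_number: int = 1

    def residue_by_key(self, key: tuple[str, int, str]) -> ResidueRecord:
        for res in self.residues:
            if res.key == key:
                return res
        raise KeyError(f"residue {key} not in model {self.structure_id}")


@dataclass
class PocketDefinition:
    """The residue set within ``cutoff`` Å of one ligand's heavy atoms."""

    pocket_id: str
    residue_keys: list[tuple[str, int, str]]
    cutoff: float
    ligand_ref: str
    res_types: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residue_keys)

    def residues(self, model: StructureModel) -> list[ResidueRecord]:
        return [model.residue_by_key(k) for k in self.residue_keys]


# ---------------------------------------------------------------------------
# parsing


def _resolve_altlocs(residue: gemmi.Residue) -> list[AtomRecord]:
    """Collapse alternate locations: keep, per atom name, the conformer with
    the highest occupancy (lexicographically smallest altloc id on ties)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        else:
            if (atom.occ, _altloc_rank(prev)) > (prev.occ, _altloc_rank(atom)):
                best[atom.name] = atom
    records = []
    for atom in best.values():
        records.append(
            AtomRecord(
                name=atom.name,
                element=atom.element.name or atom.name[:1],
                coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                occupancy=atom.occ,
            )
        )
    return records


def _altloc_rank(atom: gemmi.Atom) -> int:
    # Higher rank = preferred on occupancy ties; '\0' (no altloc) wins, then 'A' < 'B'.
    c = atom.altloc
    return 0 if c == "\0" else -ord(c)


_STANDARD_POLYMER = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL
       MSE A C G U DA DC DG DT DI""".split()
)


def parse_structure(
    source: Union[str, Path],
    fmt: Optional[str] = None,
    structure_id: Optional[str] = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file (path or raw text) into a :class:`StructureModel`.

    Only the first coordinate model is kept. Alternate locations are resolved
    to the highest-occupancy conformer. Hydrogens are retained on the atom
    lists but excluded from every distance rule downstream.

    Parameters
    ----------
    source:
        Path to a coordinate file, or the file content itself (detected by
        the presence of newlines).
    fmt:
        ``"pdb"`` or ``"mmcif"``; inferred from the file suffix or content
        when omitted.
    """
    text: Optional[str] = None
    path: Optional[Path] = None
    if isinstance(source, Path):
        path = source
    elif "\n" in source:
        text = source
    else:
        path = Path(source)

    if fmt is None:
        if path is not None:
            suffix = path.suffix.lower()
            fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
        else:
            fmt = "mmcif" if text.lstrip().startswith(("data_", "#")) else "pdb"
    fmt = fmt.lower()
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown coordinate format {fmt!r}")

    try:
        if text is None:
            text = Path(path).read_text()
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {fmt} input: {exc}") from exc

    if len(st) == 0:
        raise EmptyModelError("structure contains no coordinate model")
    model = st[0]

    sid = structure_id or st.name or (path.stem if path else "structure")
    residues: list[ResidueRecord] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        for res in chain:
            atoms = _resolve_altlocs(res)
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            is_het = res.het_flag == "H" or (
                res.het_flag == "\0" and res.name not in _STANDARD_POLYMER
            )
            if is_het:
                ligands.append(
                    LigandInstance(
                        het_code=res.name,
                        chain=chain.name,
                        seq_number=res.seqid.num,
                        insertion_code=icode,
                        atoms=atoms,
                    )
                )
            else:
                residues.append(
                    ResidueRecord(
                        chain=chain.name,
                        seq_number=res.seqid.num,
                        insertion_code=icode,
                        res_type=res.name,
                        atoms=atoms,
                    )
                )
    if not residues and not ligands:
        raise EmptyModelError(f"structure {sid!r} contains no residues")
    return StructureModel(structure_id=sid, residues=residues, ligands=ligands, model_number=1)


# ---------------------------------------------------------------------------
# ligand enumeration and pocket extraction


def list_ligand_instances(
    model: StructureModel,
    min_heavy_atoms: int = 6,
    exclude: Optional[Iterable[str]] = None,
) -> list[LigandInstance]:
    """Enumerate candidate co-crystal ligands of the model.

    Hetero groups on the exclusion list (waters, common ions, crystallization
    additives by default) or with fewer than ``min_heavy_atoms`` heavy atoms
    are dropped; the rest are returned ordered by locator.
    """
    excluded = DEFAULT_EXCLUDED_HET_CODES if exclude is None else frozenset(exclude)
    hits = [
        lig
        for lig in model.ligands
        if lig.het_code not in excluded and len(lig.heavy_atoms()) >= min_heavy_atoms
    ]
    hits.sort(key=lambda lig: (lig.chain, lig.seq_number, lig.insertion_code))
    return hits


def extract_pocket(
    model: StructureModel,
    ligand: LigandInstance,
    cutoff: float = 6.0,
) -> PocketDefinition:
    """Extract the binding pocket of ``ligand``: all polymer residues whose
    nearest heavy atom lies within ``cutoff`` Å (inclusive) of any ligand
    heavy atom. Hydrogens are ignored on both sides; hetero groups are never
    pocket members. Residues from any chain may qualify.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_xyz = ligand.heavy_coords()
    if lig_xyz.size == 0:
        raise InvalidLigandError(f"ligand {ligand.het_code} {ligand.locator} has no heavy atoms")

    keys: list[tuple[str, int, str]] = []
    types: list[str] = []
    for res in model.residues:
        res_xyz = res.heavy_coords()
        if res_xyz.size == 0:
            continue
        d2 = np.sum((res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=-1)
        if np.sqrt(d2.min()) <= cutoff:
            keys.append(res.key)
            types.append(res.res_type)
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    keys = [keys[i] for i in order]
    types = [types[i] for i in order]
    pocket_id = f"{model.structure_id}_{ligand.het_code}_{ligand.chain}{ligand.seq_number}"
    return PocketDefinition(
        pocket_id=pocket_id,
        residue_keys=keys,
        cutoff=cutoff,
        ligand_ref=f"{ligand.het_code}:{ligand.locator}",
        res_types=types,
    )


# ---------------------------------------------------------------------------
# writers


def write_pdb(model: StructureModel, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a model as PDB text (ATOM for polymer, HETATM for ligands)."""
    lines: list[str] = []
    serial = 1

    def _fmt(record: str, atom: AtomRecord, resname: str, chain: str, seq: int, icode: str) -> str:
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        return (
            f"{record:<6s}{serial:5d} {name:<4s} {resname:>3s} {chain:1s}"
            f"{seq:4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
        )

    for res in model.residues:
        for atom in res.atoms:
            lines.append(_fmt("ATOM", atom, res.res_type, res.chain, res.seq_number, res.insertion_code))
            serial += 1
    for lig in model.ligands:
        for atom in lig.atoms:
            lines.append(_fmt("HETATM", atom, lig.het_code, lig.chain, lig.seq_number, lig.insertion_code))
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def pocket_to_json(pocket: PocketDefinition) -> str:
    payload = {
        "pocket_id": pocket.pocket_id,
        "ligand_ref": pocket.ligand_ref,
        "cutoff": pocket.cutoff,
        "residues": [
            {"chain": c, "seq_number": s, "insertion_code": i, "res_type": t}
            for (c, s, i), t in zip(pocket.residue_keys, pocket.res_types)
        ],
    }
    return json.dumps(payload, indent=2)


def pocket_from_json(text: str) -> PocketDefinition:
    payload = json.loads(text)
    return PocketDefinition(
        pocket_id=payload["pocket_id"],
        ligand_ref=payload["ligand_ref"],
        cutoff=payload["cutoff"],
        residue_keys=[(r["chain"], r["seq_number"], r["insertion_code"]) for r in payload["residues"]],
        res_types=[r["res_type"] for r in payload["residues"]],
    )


def pocket_to_tsv(pocket: PocketDefinition, structure_id: str) -> str:
    rows = ["structure_id\tchain\tseq_number\tres_type"]
    for (chain, seq, _icode), res_type in zip(pocket.residue_keys, pocket.res_types):
        rows.append(f"{structure_id}\t{chain}\t{seq}\t{res_type}")
    return "\n".join(rows) + "\n"
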