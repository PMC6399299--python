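"""Synthetic fixtures with known ground truth for every pipeline stage.

Three families of generators:

* toy protein–ligand complexes whose pocket membership is known by
  construction (nearest heavy-atom distances are planted exactly), plus a
  perturbation operator for planted-similarity recovery experiments;
* compound tables whose drug-like / duplicate composition is planted, so
  filter and deduplication outputs can be checked against exact survivor
  sets;
* assay curves (logistic polymerization kinetics, dose-dependent growth
  and death series) with analytically known Vmax, MEP, fold changes and
  EC50s.

Geometric realism is *not* attempted: residues are minimal heavy-atom
clusters (backbone anchor + side-chain template atoms with correct element
labels) placed on controlled radii around a collinear ligand, which is
sufficient for the count-based featurization schema and makes every
distance rule exactly testable. All generators are deterministic under a
fixed seed, and each returns its ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .assay_analysis import PolymerizationCurve
from .featurize import STANDARD_AMINO_ACIDS
from .pocket_similarity import ScreenHit
from .structure_io import AtomRecord, LigandInstance, ResidueRecord, StructureModel

__all__ = [
    "GeneratorConfig",
    "gen_toy_complex",
    "perturb_pocket",
    "gen_compound_table",
    "gen_screen_hits",
    "gen_polymerization",
    "gen_cell_series",
]

# Side-chain heavy-atom names of the 20 standard residues (PDB nomenclature).
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

_BACKBONE = ("N", "CA", "C", "O")


def _element_of(atom_name: str) -> str:
    return atom_name[0]


@dataclass
class GeneratorConfig:
    """Reproducibility record: seed, size/noise parameters, planted truth."""

    seed: int
    params: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "params": self.params, "ground_truth": self.ground_truth},
            indent=2,
            default=float,
        )


# ---------------------------------------------------------------------------
# toy complexes


def _unit_direction(rng: np.random.Generator) -> np.ndarray:
    """Random unit vector in a cone around +x (x component ≥ ~0.58), so all
    residue atoms stay strictly in the half-space opposite the ligand tail
    and the planted nearest-atom distances hold exactly."""
    v = np.clip(rng.normal(size=3), -2.0, 2.0)
    v[0] = abs(v[0]) + 2.0
    return v / np.linalg.norm(v)


def _build_residue(
    rng: np.random.Generator,
    chain: str,
    seq: int,
    res_type: str,
    direction: np.ndarray,
    anchor_distance: float,
) -> ResidueRecord:
    """A residue whose nearest heavy atom (CA) sits at exactly
    ``anchor_distance`` from the origin along ``direction``; every other
    atom is strictly farther from the origin."""
    u = direction
    # Orthonormal frame for small lateral offsets.
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    atoms = [AtomRecord("CA", "C", tuple(anchor_distance * u))]
    for j, name in enumerate(("N", "C", "O")):
        radial = anchor_distance + 0.6 + 0.45 * j
        lateral = 0.5 * rng.uniform(-1, 1) * e1 + 0.5 * rng.uniform(-1, 1) * e2
        atoms.append(AtomRecord(name, _element_of(name), tuple(radial * u + lateral)))
    for j, name in enumerate(SIDE_CHAIN_ATOMS[res_type]):
        radial = anchor_distance + 1.2 + 0.4 * j
        lateral = 0.7 * rng.uniform(-1, 1) * e1 + 0.7 * rng.uniform(-1, 1) * e2
        atoms.append(AtomRecord(name, _element_of(name), tuple(radial * u + lateral)))
    return ResidueRecord(chain=chain, seq_number=seq, res_type=res_type, atoms=atoms)


def gen_toy_complex(
    n_pocket_residues: int,
    n_decoy_residues: int = 0,
    seed: int = 0,
    pocket_distances: Optional[Sequence[float]] = None,
    ligand_heavy_atoms: int = 8,
    structure_id: Optional[str] = None,
) -> StructureModel:
    """A toy complex: one ligand near the origin plus residues at planted
    nearest-heavy-atom distances.

    Ligand atoms lie on the non-positive x axis with one atom exactly at
    the origin, and all residue atoms have positive x, so each residue's
    minimum heavy-atom distance to the ligand equals its planted anchor
    distance exactly. Pocket residues default to distances sampled in
    [3.0, 5.8] Å (within the 6 Å rule); decoys sample [7.5, 12.0] Å.
    """
    if n_pocket_residues < 1:
        raise ValueError("need at least one pocket residue")
    rng = np.random.default_rng(seed)
    if pocket_distances is None:
        pocket_distances = rng.uniform(3.0, 5.8, size=n_pocket_residues)
    elif len(pocket_distances) != n_pocket_residues:
        raise ValueError("pocket_distances length must equal n_pocket_residues")
    decoy_distances = rng.uniform(7.5, 12.0, size=n_decoy_residues)

    elements = ["C", "C", "O", "N", "C", "C", "O", "C"]
    lig_atoms = [
        AtomRecord(f"{elements[i % 8]}{i + 1}", elements[i % 8], (-0.5 * i, 0.0, 0.0))
        for i in range(ligand_heavy_atoms)
    ]
    ligand = LigandInstance(het_code="LIG", chain="B", seq_number=900, atoms=lig_atoms)

    residues = []
    seq = 1
    for dist in list(pocket_distances) + list(decoy_distances):
        res_type = STANDARD_AMINO_ACIDS[rng.integers(len(STANDARD_AMINO_ACIDS))]
        residues.append(
            _build_residue(rng, "A", seq, res_type, _unit_direction(rng), float(dist))
        )
        seq += 1
    return StructureModel(
        structure_id=structure_id or f"TOY{seed}",
        residues=residues,
        ligands=[ligand],
    )


def perturb_pocket(
    model: StructureModel,
    jitter_sd: float = 0.0,
    relabel_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, dict]:
    """Noisy copy of a model: Gaussian coordinate jitter on all residue
    atoms and random residue-type relabeling of a fraction of residues.

    Returns the perturbed model and a ground-truth record of what changed.
    The ligand is left untouched so pocket extraction stays anchored.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if not 0 <= relabel_fraction <= 1:
        raise ValueError("relabel_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(model.residues)
    n_relabel = int(round(relabel_fraction * n))
    relabel_idx = set(rng.choice(n, size=n_relabel, replace=False)) if n_relabel else set()

    new_residues = []
    relabeled: list[tuple[str, int, str]] = []
    for i, res in enumerate(model.residues):
        res_type = res.res_type
        atoms = res.atoms
        if i in relabel_idx:
            choices = [a for a in STANDARD_AMINO_ACIDS if a != res.res_type]
            res_type = choices[rng.integers(len(choices))]
            relabeled.append(res.key)
            atoms = _retype_atoms(atoms, res_type)
        new_atoms = []
        for atom in atoms:
            coords = np.asarray(atom.coords) + rng.normal(0.0, jitter_sd, size=3)
            new_atoms.append(AtomRecord(atom.name, atom.element, tuple(coords), atom.occupancy))
        new_residues.append(
            ResidueRecord(
                chain=res.chain,
                seq_number=res.seq_number,
                insertion_code=res.insertion_code,
                res_type=res_type,
                atoms=new_atoms,
            )
        )
    perturbed = StructureModel(
        structure_id=model.structure_id + "_pert",
        residues=new_residues,
        ligands=model.ligands,
    )
    truth = {
        "jitter_sd": jitter_sd,
        "relabel_fraction": relabel_fraction,
        "relabeled_residues": relabeled,
    }
    return perturbed, truth


def _retype_atoms(atoms: Sequence[AtomRecord], new_type: str) -> list[AtomRecord]:
    """Swap a residue's side chain for the new type's template, reusing the
    old side-chain positions where available and extending outward from CA
    otherwise."""
    backbone = [a for a in atoms if a.name in _BACKBONE]
    old_side = [a for a in atoms if a.name not in _BACKBONE]
    ca = next((a for a in atoms if a.name == "CA"), atoms[0])
    ca_pos = np.asarray(ca.coords)
    if old_side:
        direction = np.mean([a.coords for a in old_side], axis=0) - ca_pos
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    else:
        direction = np.array([1.0, 0.0, 0.0])
    new_side = []
    for j, name in enumerate(SIDE_CHAIN_ATOMS[new_type]):
        if j < len(old_side):
            pos = old_side[j].coords
        else:
            pos = tuple(ca_pos + (1.5 + 0.4 * j) * direction)
        new_side.append(AtomRecord(name, _element_of(name), pos))
    return backbone + new_side


# ---------------------------------------------------------------------------
# compound tables


def gen_compound_table(
    n: int,
    druglike_fraction: float = 0.5,
    dup_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list, dict]:
    """A compound table with planted drug-likeness and duplication.

    Exactly ``round(n * druglike_fraction)`` records pass the drug-like
    filter (violations < 2 and MW in the 170–1000 Da window); the rest
    fail it unambiguously (out-of-window MW or two simultaneous rule
    violations). ``round(n * dup_fraction)`` records are duplicates that
    share the structure key (and descriptors) of an earlier original with
    the same drug-likeness. The ground truth lists the expected survivors
    of filter and dedupe, separately and combined.
    """
    from .compound_prep import CompoundRecord  # local import to avoid cycle

    if not 0 <= druglike_fraction <= 1 or not 0 <= dup_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if n == 0:
        return [], {"druglike_ids": [], "unique_ids": [], "survivor_ids": []}
    rng = np.random.default_rng(seed)
    n_druglike = int(round(n * druglike_fraction))
    n_dup = int(round(n * dup_fraction))

    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:n_druglike]] = True
    # One guaranteed original per flag group; duplicates copy from it.
    group_first: dict[bool, int] = {}
    for i, f in enumerate(flags):
        group_first.setdefault(bool(f), i)
    candidates = [i for i in range(n) if i != group_first.get(bool(flags[i]))]
    n_dup = min(n_dup, len(candidates))
    dup_slots = set(rng.choice(candidates, size=n_dup, replace=False)) if n_dup else set()

    def _draw_druglike() -> dict:
        if rng.random() < 0.3:  # single-violation drug-like record (MW > 500)
            return {
                "mw": rng.uniform(520, 950),
                "logp": rng.uniform(0, 4.5),
                "hbd": int(rng.integers(0, 6)),
                "hba": int(rng.integers(0, 11)),
            }
        return {
            "mw": rng.uniform(200, 480),
            "logp": rng.uniform(0, 4.5),
            "hbd": int(rng.integers(0, 6)),
            "hba": int(rng.integers(0, 11)),
        }

    def _draw_nondruglike() -> dict:
        mode = rng.integers(3)
        if mode == 0:  # above the MW window
            return {"mw": rng.uniform(1010, 1600), "logp": rng.uniform(0, 4.5),
                    "hbd": int(rng.integers(0, 6)), "hba": int(rng.integers(0, 11))}
        if mode == 1:  # below the MW window
            return {"mw": rng.uniform(60, 165), "logp": rng.uniform(0, 4.5),
                    "hbd": int(rng.integers(0, 6)), "hba": int(rng.integers(0, 11))}
        # two violations inside the window
        return {"mw": rng.uniform(520, 990), "logp": rng.uniform(5.5, 9.0),
                "hbd": int(rng.integers(0, 6)), "hba": int(rng.integers(0, 11))}

    records = []
    originals: dict[int, CompoundRecord] = {}
    for i in range(n):
        if i in dup_slots:
            src = originals[group_first[bool(flags[i])]]
            rec = CompoundRecord(
                ligand_id=f"CMP{i:05d}",
                mw=src.mw,
                logp=src.logp,
                hbd=src.hbd,
                hba=src.hba,
                structure_key=src.structure_key,
            )
        else:
            desc = _draw_druglike() if flags[i] else _draw_nondruglike()
            rec = CompoundRecord(
                ligand_id=f"CMP{i:05d}", structure_key=f"KEY{i:05d}-{seed}", **desc
            )
            originals[i] = rec
        records.append(rec)

    druglike_ids = [records[i].ligand_id for i in range(n) if flags[i]]
    unique_ids = [records[i].ligand_id for i in range(n) if i not in dup_slots]
    survivor_ids = [
        records[i].ligand_id for i in range(n) if flags[i] and i not in dup_slots
    ]
    truth = {
        "druglike_ids": druglike_ids,
        "unique_ids": unique_ids,
        "survivor_ids": survivor_ids,
    }
    return records, truth


def gen_screen_hits(
    n: int = 36,
    family_probs: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[ScreenHit], dict]:
    """Annotated screen hits drawn from a planted target-family multinomial.

    The default family mix mirrors a repurposing screen dominated by
    estrogen receptors, with tubulins, MAPK14 kinases and DHODHs as the
    next most frequent cognate targets.
    """
    if family_probs is None:
        family_probs = {"ER": 12 / 36, "TUB": 4 / 36, "MAPK14": 4 / 36,
                        "DHODH": 3 / 36, "other": 13 / 36}
    rng = np.random.default_rng(seed)
    families = sorted(family_probs)
    probs = np.array([family_probs[f] for f in families])
    probs = probs / probs.sum()
    draws = rng.choice(len(families), size=n, p=probs)
    hits = []
    for i, d in enumerate(draws):
        pfs = float(rng.uniform(-6.0, -3.6))
        hits.append(
            ScreenHit(
                pocket_id=f"HIT{i:03d}",
                pfs=pfs,
                significant=True,
                cognate_ligand=f"LG{i:03d}",
                target_family=families[d],
            )
        )
    counts = {f: int((draws == i).sum()) for i, f in enumerate(families) if (draws == i).any()}
    return hits, {"family_counts": counts}


# ---------------------------------------------------------------------------
# polymerization curves


def _shaped_logistic(t: np.ndarray, r: float, t0: float, t_end: float) -> np.ndarray:
    """Logistic rescaled to run exactly from 0 at t=0 to 1 at t=t_end."""
    lo, hi = expit(-r * t0), expit(r * (t_end - t0))
    return (expit(r * (t - t0)) - lo) / (hi - lo)


def _solve_rate(v_true: float, plateau: float, t0: float, t_end: float) -> float:
    """Logistic rate such that the curve's analytic maximum slope is v_true.

    The maximum slope of the rescaled logistic is plateau*r / (4*span); it
    approaches plateau/t_end (a straight line) as r -> 0, so the requested
    Vmax must exceed that.
    """
    if v_true <= plateau / t_end:
        raise ValueError(
            f"v_true={v_true} is unreachable for plateau={plateau} over {t_end} min "
            f"(needs v_true > {plateau / t_end:.3f})"
        )

    def max_slope(r: float) -> float:
        span = expit(r * (t_end - t0)) - expit(-r * t0)
        return plateau * r / (4.0 * span)

    return brentq(lambda r: max_slope(r) - v_true, 1e-9, 50.0)


def gen_polymerization(
    v_true: float = 2.8,
    plateau: float = 34.5,
    noise_sd: float = 0.0,
    n_timepoints: int = 61,
    seed: int = 0,
    condition: str = "TEST",
    t_end: float = 30.0,
    reference: tuple[float, float] = (5.8, 100.0),
    control: tuple[float, float] = (1.0, 20.5),
) -> tuple[list[PolymerizationCurve], dict]:
    """A polymerization run: paclitaxel-like reference, DMSO-like control,
    and one test condition with planted Vmax (%/min) and plateau (% of the
    reference end point).

    Curves are logistic, anchored at exactly 0% at t=0 and their plateau at
    t=30 min, emitted as raw fluorescence AU (offset 0.05, gain 0.01 AU/%)
    with additive Gaussian noise, so the normalization step has real work
    to do. Ground truth (exact for the noiseless curves): per-condition
    Vmax and MEP, and fold changes over the control. Defaults emulate a
    raloxifene-like enhancer read at 30 s intervals; the control Vmax and
    MEP mirror a vehicle run.
    """
    if plateau <= 0:
        raise ValueError("plateau must be positive")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_timepoints)
    t0 = 0.35 * t_end
    specs = {
        "TAX": reference,
        "DMSO": control,
        condition: (v_true, plateau),
    }
    curves = []
    truth_vmax = {}
    truth_mep = {}
    for name, (v, p) in specs.items():
        r = _solve_rate(v, p, t0, t_end)
        pct = p * _shaped_logistic(times, r, t0, t_end)
        raw = 0.05 + 0.01 * pct + rng.normal(0.0, 0.01 * noise_sd, size=times.shape)
        curves.append(PolymerizationCurve(condition=name, times=times, readings=raw))
        truth_vmax[name] = v
        truth_mep[name] = p
    truth = {
        "vmax": truth_vmax,
        "mep": truth_mep,
        "fc_vmax": {k: truth_vmax[k] / truth_vmax["DMSO"] for k in specs},
        "fc_mep": {k: truth_mep[k] / truth_mep["DMSO"] for k in specs},
        "noise_sd": noise_sd,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# live-cell dose-response series


def gen_cell_series(
    ec50_true: float = 25.0,
    hill: float = 1.5,
    vehicle_slope: float = 1.0,
    noise_sd: float = 0.0,
    doses: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_timepoints: int = 25,
    t_max_h: float = 48.0,
    death_ceiling: float = 0.9,
    death_noise_sd: float = 0.0,
) -> tuple[dict, dict, tuple, dict]:
    """Dose-dependent proliferation and death series with planted EC50s.

    Growth: per-dose confluence is linear in time with slope following a
    descending 4PL in log dose (midpoint ``ec50_true`` µM). Death: the dead
    fraction at 24 h and 48 h follows an ascending 4PL with the same
    midpoint and ceiling ``death_ceiling``. Gaussian noise is added to
    confluence (``noise_sd``, percentage points) and to dead fractions
    (``death_noise_sd``, fraction units, clipped to [0, 1]). Truth marks an
    EC50 "not assigned" (None) when it falls outside the dose range, where
    no bracket exists.

    Returns (growth series {dose: (times, confluence)}, death series
    {"24": (doses, fractions), "48": ...}, vehicle series, truth).
    """
    if doses is None:
        doses = np.logspace(0, np.log10(200.0), 8)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_max_h, n_timepoints)

    vehicle = (times, 10.0 + vehicle_slope * times + rng.normal(0, noise_sd, times.shape))
    growth = {}
    for c in doses:
        slope = vehicle_slope / (1.0 + (c / ec50_true) ** hill)
        conf = 10.0 + slope * times + rng.normal(0, noise_sd, times.shape)
        growth[float(c)] = (times, conf)

    death = {}
    for label in ("24", "48"):
        frac = death_ceiling / (1.0 + (ec50_true / doses) ** hill)
        if death_noise_sd:
            frac = np.clip(frac + rng.normal(0, death_noise_sd, doses.shape), 0.0, 1.0)
        death[label] = (doses.copy(), frac)

    in_range = doses.min() <= ec50_true <= doses.max()
    truth = {
        "ec50_p": ec50_true if in_range else None,
        "ec50_d24": ec50_true if in_range else None,
        "ec50_d48": ec50_true if in_range else None,
        "hill": hill,
        "vehicle_slope": vehicle_slope,
    }
    return growth, death, vehicle, truth
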