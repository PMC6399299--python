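import numpy as np
import pytest

from pocketscreen import featurize, structure_io, synthetic_data
from pocketscreen.structure_io import AtomRecord, LigandInstance, ResidueRecord, StructureModel


@pytest.fixture(scope="session")
def schema():
    return featurize.default_schema()


@pytest.fixture
def toy_model():
    """Deterministic 8-residue complex with planted pocket distances."""
    return synthetic_data.gen_toy_complex(
        8, 0, seed=1, pocket_distances=[3, 4, 5, 5.5, 6.0, 6.5, 8, 10]
    )


def make_residue(res_type, chain="A", seq=1, atoms=()):
    return ResidueRecord(
        chain=chain,
        seq_number=seq,
        res_type=res_type,
        atoms=[AtomRecord(n, e, tuple(c)) for n, e, c in atoms],
    )


def make_ligand(coords, het_code="LIG", chain="B", seq=900, element="C"):
    atoms = [AtomRecord(f"{element}{i+1}", element, tuple(c)) for i, c in enumerate(coords)]
    return LigandInstance(het_code=het_code, chain=chain, seq_number=seq, atoms=atoms)


def pocket_features(model, cutoff=6.0, schema=None):
    """Extract + featurize the first qualifying ligand's pocket."""
    lig = structure_io.list_ligand_instances(model)[0]
    pocket = structure_io.extract_pocket(model, lig, cutoff=cutoff)
    return featurize.featurize_pocket(model, pocket, schema=schema, exclude_ligand=lig)


def rigid_transform(model, rotation, translation):
    """Apply a rigid transform to every atom of a model."""
    rotation = np.asarray(rotation)
    translation = np.asarray(translation)

    def move(atom):
        return AtomRecord(
            atom.name, atom.element, tuple(rotation @ np.asarray(atom.coords) + translation),
            atom.occupancy,
        )

    residues = [
        ResidueRecord(
            chain=r.chain, seq_number=r.seq_number, insertion_code=r.insertion_code,
            res_type=r.res_type, atoms=[move(a) for a in r.atoms],
        )
        for r in model.residues
    ]
    ligands = [
        LigandInstance(
            het_code=l.het_code, chain=l.chain, seq_number=l.seq_number,
            insertion_code=l.insertion_code, atoms=[move(a) for a in l.atoms],
        )
        for l in model.ligands
    ]
    return StructureModel(
        structure_id=model.structure_id, residues=residues, ligands=ligands,
        model_number=model.model_number,
    )


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
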