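"""PFS-annotated chemical similarity network.

Compounds become nodes; an undirected edge joins two compounds whose
circular-fingerprint Tanimoto coefficient exceeds 0.75 (strict). Nodes are
classed by their pocket-similarity score: ``high_sim`` for PFS < -3,
``low_sim`` for PFS > -2, ``intermediate`` for the band in between, and
``unscored`` when no PFS is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .pocket_similarity import tanimoto

__all__ = [
    "FingerprintVector",
    "CompoundNetwork",
    "TC_EDGE_THRESHOLD",
    "PFS_COLOR_BANDS",
    "fingerprint",
    "tanimoto_chem",
    "classify_pfs",
    "build_network",
]

#: Chemical-similarity edge threshold (strict '>').
TC_EDGE_THRESHOLD = 0.75
#: PFS color bands: below the first value = high similarity (red),
#: above the second = low similarity (blue).
PFS_COLOR_BANDS = (-3.0, -2.0)


@dataclass
class FingerprintVector:
    """Hashed circular (Morgan) fingerprint of one compound."""

    ligand_id: str
    bits: np.ndarray
    radius: int = 2
    n_bits: int = 2048


@dataclass
class CompoundNetwork:
    """Thin wrapper around the underlying :class:`networkx.Graph`."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["tc"]) for u, v, d in self.graph.edges(data=True)]

    def color_class(self, ligand_id: str) -> str:
        return self.graph.nodes[ligand_id]["color_class"]

    def components(self) -> list[frozenset[str]]:
        return sorted(
            (frozenset(c) for c in nx.connected_components(self.graph)),
            key=lambda c: sorted(c),
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def edge_list_tsv(self) -> str:
        rows = ["id_a\tid_b\ttc"]
        for u, v, tc in sorted(self.edges):
            rows.append(f"{u}\t{v}\t{tc:.4f}")
        return "\n".join(rows) + "\n"

    def node_table_tsv(self) -> str:
        rows = ["ligand_id\tpfs\tcolor_class"]
        for n, data in sorted(self.graph.nodes(data=True)):
            pfs = data.get("pfs")
            rows.append(f"{n}\t{'' if pfs is None else f'{pfs:.4f}'}\t{data['color_class']}")
        return "\n".join(rows) + "\n"


def fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 2048, ligand_id: str = ""
) -> FingerprintVector:
    """Hashed circular-neighborhood fingerprint of a SMILES string.

    Canonical with respect to atom input order: any SMILES of the same
    molecular graph yields the same bit vector.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r} (ligand {ligand_id or '?'})")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = gen.GetFingerprintAsNumPy(mol).astype(np.uint8)
    return FingerprintVector(ligand_id=ligand_id or smiles, bits=bits, radius=radius, n_bits=n_bits)


def tanimoto_chem(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient between two fingerprints of equal length."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    return tanimoto(a.bits, b.bits)


def classify_pfs(
    pfs: Optional[float], bands: tuple[float, float] = PFS_COLOR_BANDS
) -> str:
    """PFS color class: high_sim / low_sim / intermediate / unscored."""
    lo, hi = bands
    if pfs is None:
        return "unscored"
    if pfs < lo:
        return "high_sim"
    if pfs > hi:
        return "low_sim"
    return "intermediate"


def build_network(
    compounds: Sequence[tuple[str, str]],
    pfs_map: Optional[Mapping[str, float]] = None,
    tc_threshold: float = TC_EDGE_THRESHOLD,
    bands: tuple[float, float] = PFS_COLOR_BANDS,
    radius: int = 2,
    n_bits: int = 2048,
) -> CompoundNetwork:
    """All-pairs chemical similarity network over (ligand_id, SMILES) pairs.

    Edges require Tc strictly above ``tc_threshold``; node color classes
    come from ``pfs_map`` via :func:`classify_pfs`.
    """
    ids = [lid for lid, _ in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("ligand ids must be unique")
    pfs_map = pfs_map or {}
    fps = [fingerprint(smi, radius=radius, n_bits=n_bits, ligand_id=lid) for lid, smi in compounds]

    g = nx.Graph()
    for fp in fps:
        pfs = pfs_map.get(fp.ligand_id)
        g.add_node(fp.ligand_id, color_class=classify_pfs(pfs, bands))
        if pfs is not None:
            g.nodes[fp.ligand_id]["pfs"] = float(pfs)
    for fa, fb in combinations(fps, 2):
        tc = tanimoto_chem(fa, fb)
        if tc > tc_threshold:
            g.add_edge(fa.ligand_id, fb.ligand_id, tc=float(tc))
    return CompoundNetwork(graph=g)
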