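"""Pocket-pair scoring: Tanimoto similarity, optimal residue matching, PFS.

Two pockets are compared by their residue microenvironment bit vectors. The
pairwise Tanimoto matrix feeds a maximum-weight one-to-one assignment; pairs
below the inclusion cutoff ``tau`` are dropped, and the PocketFeature Score
(PFS) is the negated sum of the matched similarities. More negative means
more similar: a self-comparison of an n-residue pocket with distinct
residues scores exactly -n, unrelated pockets score near 0, and screens
call a hit significant at PFS < -3.5 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .featurize import PocketFeatureSet, SchemaMismatchError

__all__ = [
    "PairScoreMatrix",
    "PocketAlignment",
    "ScreenHit",
    "PFS_SIGNIFICANCE_THRESHOLD",
    "tanimoto",
    "pair_score_matrix",
    "optimal_assignment",
    "align_pockets",
    "pfs_significant",
    "screen_database",
]

logger = logging.getLogger(__name__)

#: Screening significance cutoff on the PocketFeature Score (strict '<').
PFS_SIGNIFICANCE_THRESHOLD = -3.5


def tanimoto(bits_a: np.ndarray, bits_b: np.ndarray) -> float:
    """Tanimoto coefficient |A∧B| / |A∨B| of two equal-length bit vectors.

    Defined as 0.0 when both vectors are all-zero.
    """
    a = np.asarray(bits_a).astype(bool)
    b = np.asarray(bits_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"bit-vector length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class PairScoreMatrix:
    """All-pairs Tanimoto similarities between the residues of two pockets."""

    rows: list[tuple[str, int, str]]
    cols: list[tuple[str, int, str]]
    T: np.ndarray


@dataclass
class PocketAlignment:
    """A one-to-one residue matching between two pockets and its PFS."""

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str], float]]
    tau: float
    pfs: float
    pocket_a: str = ""
    pocket_b: str = ""


@dataclass
class ScreenHit:
    """One database entry's score against the query pocket."""

    pocket_id: str
    pfs: float
    significant: bool
    cognate_ligand: Optional[str] = None
    target_family: Optional[str] = None


def pair_score_matrix(fs_a: PocketFeatureSet, fs_b: PocketFeatureSet) -> PairScoreMatrix:
    """Vectorized all-pairs Tanimoto between two feature sets (same schema)."""
    if fs_a.schema_id != fs_b.schema_id:
        raise SchemaMismatchError(
            f"cannot compare schema {fs_a.schema_id!r} with {fs_b.schema_id!r}"
        )
    A = fs_a.bit_matrix().astype(np.int32)
    B = fs_b.bit_matrix().astype(np.int32)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return PairScoreMatrix(
        rows=[m.residue_ref for m in fs_a.microenvironments],
        cols=[m.residue_ref for m in fs_b.microenvironments],
        T=T,
    )


def optimal_assignment(T: np.ndarray, tau: float) -> tuple[list[tuple[int, int]], float]:
    """Maximum-weight one-to-one matching over pairs with similarity ≥ tau.

    Entries below ``tau`` are zeroed before the Hungarian assignment, so a
    sub-``tau`` pair can never improve the objective; any such pair in the
    raw assignment is dropped afterwards. Returns the matched index pairs
    in lexicographic (row, col) order and the PFS (negated matched sum).
    """
    T = np.asarray(T, dtype=float)
    clipped = np.where(T >= tau, T, 0.0)
    row_ind, col_ind = linear_sum_assignment(clipped, maximize=True)
    pairs = [(int(i), int(j)) for i, j in sorted(zip(row_ind, col_ind)) if T[i, j] >= tau]
    pfs = -float(sum(T[i, j] for i, j in pairs))
    return pairs, pfs


def align_pockets(
    fs_a: PocketFeatureSet, fs_b: PocketFeatureSet, tau: float = 0.5
) -> PocketAlignment:
    """Optimal one-to-one residue matching between two pockets.

    Maximum-weight bipartite assignment on the pairwise Tanimoto matrix;
    only pairs with similarity ≥ ``tau`` are included, and
    PFS = -Σ matched Tanimoto.
    """
    if len(fs_a) == 0 or len(fs_b) == 0:
        raise ValueError("cannot align an empty pocket")
    mat = pair_score_matrix(fs_a, fs_b)
    idx_pairs, pfs = optimal_assignment(mat.T, tau)
    pairs = [(mat.rows[i], mat.cols[j], float(mat.T[i, j])) for i, j in idx_pairs]
    return PocketAlignment(
        pairs=pairs,
        tau=tau,
        pfs=pfs,
        pocket_a=fs_a.pocket_id,
        pocket_b=fs_b.pocket_id,
    )


def pfs_significant(pfs: float, threshold: float = PFS_SIGNIFICANCE_THRESHOLD) -> bool:
    """True iff the score is strictly below the significance threshold."""
    return pfs < threshold


def screen_database(
    query: PocketFeatureSet,
    db: Iterable[PocketFeatureSet],
    tau: float = 0.5,
    threshold: float = PFS_SIGNIFICANCE_THRESHOLD,
) -> list[ScreenHit]:
    """Score the query against every database pocket, most similar first.

    Returns one :class:`ScreenHit` per entry, sorted ascending by PFS with
    a stable ``pocket_id`` tie-break.
    """
    hits = []
    db = list(db)
    if not db:
        logger.warning("screen_database called with an empty pocket database")
    for entry in db:
        aln = align_pockets(query, entry, tau=tau)
        hits.append(
            ScreenHit(
                pocket_id=entry.pocket_id,
                pfs=aln.pfs,
                significant=pfs_significant(aln.pfs, threshold),
                cognate_ligand=entry.cognate_ligand,
                target_family=entry.target_family,
            )
        )
    hits.sort(key=lambda h: (h.pfs, h.pocket_id))
    return hits


def hits_to_tsv(hits: Sequence[ScreenHit]) -> str:
    rows = ["pocket_id\tcognate_ligand\ttarget_family\tpfs\tsignificant"]
    for h in hits:
        rows.append(
            f"{h.pocket_id}\t{h.cognate_ligand or ''}\t{h.target_family or ''}"
            f"\t{h.pfs:.4f}\t{int(h.significant)}"
        )
    return "\n".join(rows) + "\n"
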