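"""Rigidity analytics: superposition/RMSD, B-factor statistics, model census.

The superposition is the closed-form least-squares fit (Kabsch): the optimal
proper rotation is obtained from the SVD of the covariance matrix, with the
sign of the smallest singular vector flipped when needed so a reflection is
never returned.  Cross-model atom pairing goes by author residue numbering
and atom names after an explicit (or trivial 1:1) chain mapping, with no
outlier rejection — reported RMSDs are plain averages over the paired atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structure_io import Structure, STANDARD_AMINO_ACIDS, WATER_NAMES

__all__ = [
    "SuperpositionResult",
    "DomainStats",
    "ModelCensus",
    "pair_atoms",
    "kabsch",
    "superpose",
    "domain_bfactor",
    "model_census",
]


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid motion p -> q and the residual RMSD."""

    rot: np.ndarray      # 3x3 proper rotation, det = +1
    trans: np.ndarray    # Å
    rmsd: float          # Å
    n_atoms: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rot.T + self.trans


def pair_atoms(a: Structure, b: Structure,
               chain_map: Mapping[str, str] | None = None,
               *, atom_names: Sequence[str] | None = None
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired heavy-atom coordinate arrays from two structures.

    Atoms are matched by (mapped chain id, author residue number, insertion
    code, atom name).  ``chain_map`` maps chains of ``a`` onto chains of
    ``b``; by default chains are paired by equal id, or 1:1 in order when the
    two structures share no chain id.  ``atom_names`` restricts the match
    (e.g. ``["CA"]``).
    """
    if not a.residues or not b.residues:
        raise AnalysisError("cannot pair atoms of an empty structure")
    if chain_map is None:
        shared = set(a.chain_ids) & set(b.chain_ids)
        if shared:
            chain_map = {c: c for c in a.chain_ids if c in shared}
        else:
            chain_map = dict(zip(a.chain_ids, b.chain_ids))
    index_b: dict[tuple, np.ndarray] = {}
    for res in b.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            index_b[(res.chain_id, res.seq_id, res.ins_code, atom.name)] = atom.xyz
    pa, pb = [], []
    for res in a.residues:
        mapped = chain_map.get(res.chain_id)
        if mapped is None:
            continue
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            if atom_names is not None and atom.name not in atom_names:
                continue
            other = index_b.get((mapped, res.seq_id, res.ins_code, atom.name))
            if other is not None:
                pa.append(atom.xyz)
                pb.append(other)
    if not pa:
        raise AnalysisError(
            "no atom pairs matched; check chain mapping and residue numbering")
    return np.array(pa), np.array(pb), len(pa)


def kabsch(p: np.ndarray, q: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of point set ``p`` onto ``q``.

    Returns the proper rotation and translation minimising the RMSD of
    ``rot @ p + trans`` versus ``q``.  Degenerate (collinear or coincident)
    inputs raise.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise AnalysisError("point sets must be matching (n, 3) arrays")
    if len(p) < 3:
        raise AnalysisError("need at least 3 point pairs")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    # collinearity check: rank of the centred coordinates
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2:
        raise AnalysisError("degenerate (collinear) point set")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    diff = p0 @ rot.T - q0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(p)))
    return SuperpositionResult(rot=rot, trans=trans, rmsd=rmsd, n_atoms=len(p))


def superpose(a: Structure, b: Structure,
              chain_map: Mapping[str, str] | None = None,
              *, atom_names: Sequence[str] | None = None) -> SuperpositionResult:
    """Pair atoms of two models and superpose a onto b."""
    pa, pb, _ = pair_atoms(a, b, chain_map, atom_names=atom_names)
    return kabsch(pa, pb)


@dataclass(frozen=True)
class DomainStats:
    """Mean isotropic B over the heavy atoms of a residue range."""

    label: str
    residue_ranges: tuple[tuple[str, int, int], ...]
    mean_b: float     # Å²
    n_atoms: int


def domain_bfactor(s: Structure,
                   domains: Mapping[str, Sequence[tuple[str, int, int]]]
                   ) -> list[DomainStats]:
    """Unweighted mean B-factor per named domain.

    ``domains`` maps a label to residue ranges ``(chain, start, end)``
    (inclusive, author numbering).  Hydrogens are excluded.  An empty range
    is an error naming the offending domain.
    """
    out = []
    for label, ranges in domains.items():
        bs = []
        for chain, start, end in ranges:
            for res in s.residues:
                if res.chain_id == chain and start <= res.seq_id <= end:
                    bs.extend(a.b_iso for a in res.atoms if not a.is_hydrogen)
        if not bs:
            raise AnalysisError(f"domain {label!r} selects no atoms "
                                f"(ranges {list(ranges)})")
        out.append(DomainStats(label=label,
                               residue_ranges=tuple(tuple(r) for r in ranges),
                               mean_b=float(np.mean(bs)), n_atoms=len(bs)))
    return out


@dataclass(frozen=True)
class ModelCensus:
    """Heavy-atom counts partitioned as deposition tables report them."""

    non_h_atoms: int
    protein_atoms: int
    ligand_atoms: int
    water_atoms: int


def model_census(s: Structure) -> ModelCensus:
    """Count heavy atoms: protein (20 standard residues + MSE), water (HOH),
    ligand (everything else).  The three classes sum to the non-hydrogen
    total by construction."""
    protein = ligand = water = 0
    for res in s.residues:
        n = sum(1 for a in res.atoms if not a.is_hydrogen)
        if res.res_name in WATER_NAMES:
            water += n
        elif res.res_name in STANDARD_AMINO_ACIDS:
            protein += n
        else:
            ligand += n
    return ModelCensus(non_h_atoms=protein + ligand + water,
                       protein_atoms=protein, ligand_atoms=ligand,
                       water_atoms=water)
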