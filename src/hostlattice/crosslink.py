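"""Geometric scan for engineerable disulfide bridges in a packed lattice.

Candidate cysteine pairs are found from backbone geometry alone: two residues
can be bridged when their Cβ atoms sit 3–5 Å apart (Cα–Cα below 7.5 Å), with
the Sγ atoms modelled at ideal stereochemistry over the three staggered χ1
rotamers of each residue.  The strain score is a transparent quadratic in the
deviations from textbook disulfide geometry (Cβ–Cβ distance, Cα–Cβ–Sγ angle
114.6°, χ3 dihedral ±87°); it ranks candidates, it does not claim energies in
physical units.  Pairs may lie within one molecule (intra) or span a symmetry
mate (inter) — the latter crosslink the lattice itself, turning a floppy
fusion domain into part of the crystal scaffold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .lattice import SymOp, apply_symop, expand_neighbors
from .structure_io import Residue, Structure

__all__ = [
    "DisulfideCandidate",
    "DisulfideParams",
    "scan_disulfides",
    "score_disulfide",
    "place_sgamma",
    "reconstruct_cbeta",
]

# textbook disulfide geometry targets
CB_CB_TARGET = 3.85          # Å, Cβ–Cβ distance in native disulfides
CA_CB_SG_TARGET = 114.6      # degrees
CHI3_TARGET = 87.0           # degrees, χ3 is ±87°
SG_BOND = 1.81               # Å, Cβ–Sγ
CHI1_ROTAMERS = (-60.0, 60.0, 180.0)


@dataclass(frozen=True)
class DisulfideParams:
    """Pre-filters and score weights for the scan."""

    d_ca_max: float = 7.5
    d_cb_min: float = 3.0
    d_cb_max: float = 5.0
    w_dist: float = 1.0      # weight on (d_cb - target)², Å²
    w_angle: float = 1.0     # weight on Cα–Cβ–Sγ angle deviation², rad²
    w_chi3: float = 1.0      # weight on χ3 deviation from ±87°², rad²
    min_seq_sep: int = 2     # skip |Δseq| < this within one chain


@dataclass(frozen=True)
class DisulfideCandidate:
    """A residue pair that could be mutated to a disulfide bridge."""

    res_a: tuple[str, int]        # (chain, author seq id)
    res_b: tuple[str, int]
    name_a: str
    name_b: str
    op_b: SymOp | None            # None = same molecule
    shift: tuple[int, int, int]
    d_ca: float
    d_cb: float
    chi3: float                   # degrees, at the best rotamer combination
    energy: float                 # >= 0, unitless strain score

    @property
    def inter(self) -> bool:
        return self.op_b is not None

    def label(self) -> str:
        star = "*" if self.inter else ""
        return (f"{self.name_a}{self.res_a[1]}-"
                f"{self.name_b}{self.res_b[1]}{star}")


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _place_internal(a, b, c, bond, angle_deg, dih_deg) -> np.ndarray:
    """Place atom D given A-B-C with bond |CD|, angle B-C-D and dihedral A-B-C-D."""
    ang, dh = math.radians(angle_deg), math.radians(dih_deg)
    bc = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(dh),
                  bond * math.sin(ang) * math.sin(dh)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def reconstruct_cbeta(n, ca, c) -> np.ndarray:
    """Ideal Cβ from backbone N, CA, C (for glycine)."""
    return _place_internal(n, c, ca, 1.53, 110.5, 122.5)


def place_sgamma(n, ca, cb, chi1: float) -> np.ndarray:
    """Model Sγ at 1.81 Å from Cβ, ideal angle, given χ1 (N-CA-CB-SG)."""
    return _place_internal(n, ca, cb, SG_BOND, CA_CB_SG_TARGET, chi1)


def _chi3_deviation_deg(chi3: float) -> float:
    return min(abs(chi3 - CHI3_TARGET), abs(chi3 + CHI3_TARGET))


def score_disulfide(d_cb: float, chi3: float,
                    ang_a: float = CA_CB_SG_TARGET,
                    ang_b: float = CA_CB_SG_TARGET,
                    params: DisulfideParams = DisulfideParams()) -> float:
    """Quadratic strain score of a candidate's geometry.

    ``w_dist (d_cb - 3.85)² + w_angle Σ (ang - 114.6°)² + w_chi3 dev(χ3, ±87°)²``
    with angular deviations in radians; zero at textbook geometry.
    """
    e = params.w_dist * (d_cb - CB_CB_TARGET) ** 2
    e += params.w_angle * (math.radians(ang_a - CA_CB_SG_TARGET) ** 2
                           + math.radians(ang_b - CA_CB_SG_TARGET) ** 2)
    e += params.w_chi3 * math.radians(_chi3_deviation_deg(chi3)) ** 2
    return e


@dataclass
class _Site:
    res: Residue
    ca: np.ndarray
    cb: np.ndarray
    n: np.ndarray


def _collect_sites(s: Structure) -> tuple[list[_Site], list[str]]:
    sites, warnings = [], []
    for res in s.residues:
        if res.is_water or not res.is_amino_acid:
            continue
        ca = res.atom("CA")
        n = res.atom("N")
        c = res.atom("C")
        if ca is None or n is None:
            warnings.append(f"{res.chain_id}{res.seq_id} {res.res_name}: "
                            "missing backbone, skipped")
            continue
        cb_atom = res.atom("CB")
        if cb_atom is not None:
            cb = cb_atom.xyz
        elif c is not None:
            cb = reconstruct_cbeta(n.xyz, ca.xyz, c.xyz)
        else:
            warnings.append(f"{res.chain_id}{res.seq_id} {res.res_name}: "
                            "no CB and no C to rebuild it, skipped")
            continue
        sites.append(_Site(res=res, ca=ca.xyz, cb=cb, n=n.xyz))
    return sites, warnings


def _best_rotamer(site_a: _Site, ca_b, cb_b, n_b,
                  params: DisulfideParams) -> tuple[float, float]:
    """(chi3, energy) at the best of the 3×3 sampled χ1 rotamer pairs."""
    d_cb = float(np.linalg.norm(site_a.cb - cb_b))
    best = (0.0, math.inf)
    for chi1_a, chi1_b in product(CHI1_ROTAMERS, repeat=2):
        sg_a = place_sgamma(site_a.n, site_a.ca, site_a.cb, chi1_a)
        sg_b = place_sgamma(n_b, ca_b, cb_b, chi1_b)
        chi3 = dihedral(site_a.cb, sg_a, sg_b, cb_b)
        e = score_disulfide(d_cb, chi3, params=params)
        if e < best[1]:
            best = (chi3, e)
    return best


Mode = Literal["intra", "inter", "both"]


def scan_disulfides(s: Structure, mode: Mode = "both",
                    params: DisulfideParams = DisulfideParams(),
                    *, warnings: list | None = None
                    ) -> list[DisulfideCandidate]:
    """All residue pairs that pass the disulfide geometry pre-filters.

    ``intra`` scans pairs within the reference copy, ``inter`` scans the
    reference against every symmetry mate (cell + space group required),
    ``both`` does both.  Results are sorted by strain score, then residue
    identifiers, so the order is deterministic.  Residues lacking backbone
    atoms are skipped and reported in ``warnings``.
    """
    sites, warns = _collect_sites(s)
    if warnings is not None:
        warnings.extend(warns)
    out: list[DisulfideCandidate] = []
    if not sites:
        return out
    cb = np.array([st.cb for st in sites])

    def consider(i: int, j_site: _Site, j_key, j_name,
                 op: SymOp | None, shift, ca_b, cb_b, n_b):
        a = sites[i]
        d_ca = float(np.linalg.norm(a.ca - ca_b))
        d_cb = float(np.linalg.norm(a.cb - cb_b))
        if d_ca > params.d_ca_max:
            return
        if not params.d_cb_min <= d_cb <= params.d_cb_max:
            return
        chi3, energy = _best_rotamer(a, ca_b, cb_b, n_b, params)
        out.append(DisulfideCandidate(
            res_a=(a.res.chain_id, a.res.seq_id), res_b=j_key,
            name_a=a.res.res_name, name_b=j_name,
            op_b=op, shift=tuple(shift), d_ca=d_ca, d_cb=d_cb,
            chi3=chi3, energy=energy))

    if mode in ("intra", "both"):
        tree = cKDTree(cb)
        for i, j in sorted(tree.query_pairs(params.d_cb_max)):
            a, b = sites[i], sites[j]
            if (a.res.chain_id == b.res.chain_id
                    and abs(a.res.seq_id - b.res.seq_id) < params.min_seq_sep):
                continue
            consider(i, b, (b.res.chain_id, b.res.seq_id), b.res.res_name,
                     None, (0, 0, 0), b.ca, b.cb, b.n)
    if mode in ("inter", "both"):
        if s.cell is None or s.space_group is None:
            raise ValueError("inter-molecular scan needs cell and space group")
        # probe structure restricted to usable sites, so mate coordinates map
        # one-to-one onto the site list
        probe = Structure([st.res for st in sites], cell=s.cell,
                          space_group=s.space_group, id=s.id)
        for nb in expand_neighbors(probe, cutoff=params.d_ca_max):
            ca_m = apply_symop(nb.op, nb.shift,
                               (s.cell, np.array([st.ca for st in sites])))
            cb_m = apply_symop(nb.op, nb.shift, (s.cell, cb))
            n_m = apply_symop(nb.op, nb.shift,
                              (s.cell, np.array([st.n for st in sites])))
            mtree = cKDTree(cb_m)
            for i, js in enumerate(mtree.query_ball_point(cb, params.d_cb_max)):
                for j in js:
                    b = sites[j]
                    consider(i, b, (b.res.chain_id, b.res.seq_id),
                             b.res.res_name, nb.op, nb.shift,
                             ca_m[j], cb_m[j], n_m[j])
    out.sort(key=lambda c: (c.energy, c.res_a, c.res_b))
    return out
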