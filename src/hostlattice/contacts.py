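"""Solvent-accessible surface area and crystal-contact interface accounting.

SASA uses Shrake–Rupley sphere sampling with a deterministic golden-section
spiral point set, so repeated runs give bit-identical areas.  Buried interface
area between two selections follows the single-interface convention

    area = (SASA(A) + SASA(B) - SASA(A ∪ B)) / 2

with hydrogens excluded and, by default, only polypeptide chains considered
(waters and ligands dropped), matching how crystal-contact tables are usually
reported.  One of the two selections may live on a symmetry mate, in which
case the structure's cell and space group supply the operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .lattice import LatticeError, Neighbor, SymOp, apply_symop, expand_neighbors
from .structure_io import Structure

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "InterfaceArea",
    "sasa",
    "sasa_structure",
    "interface_area",
    "crystal_contact_table",
    "sphere_points",
]

# Fixed van der Waals radii (Å); anything unlisted falls back to the default
# unless strict element checking is requested.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral: n near-uniform points on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def atom_radii(elements: Sequence[str], *, default: float | None = DEFAULT_RADIUS
               ) -> np.ndarray:
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = el.upper()
        if key in VDW_RADII:
            out[i] = VDW_RADII[key]
        elif default is not None:
            out[i] = default
        else:
            raise LatticeError(f"no van der Waals radius for element {el!r}")
    return out


@dataclass
class SasaResult:
    """Per-atom solvent-accessible areas, Å²."""

    per_atom: np.ndarray
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _canonical_frame(xyz: np.ndarray) -> np.ndarray:
    """Rotation-covariant orthonormal frame from the coordinates themselves.

    Principal axes of the centred coordinates, each signed so the third
    moment along it is non-negative, right-handed.  Rotating the input
    rotates the frame identically, which makes the sphere sampling — and
    hence the computed areas — invariant under rigid motions of the system.
    """
    if len(xyz) < 3:
        return np.eye(3)
    c = xyz - xyz.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    vecs = vecs[:, ::-1]  # descending variance
    for j in range(3):
        if ((c @ vecs[:, j]) ** 3).sum() < 0:  # skewness fixes the sign
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def sasa(xyz: np.ndarray, elements: Sequence[str], probe: float = 1.4,
         n_points: int = 960, *, default_radius: float | None = DEFAULT_RADIUS
         ) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    For each atom, ``n_points`` spiral points are placed on the expanded
    sphere of radius ``r_vdw + probe``; the accessible area is the fraction of
    points not inside any neighbouring expanded sphere, times the sphere area.
    The point set is oriented by the system's own principal axes, so the
    result is deterministic and invariant under rigid motions.
    """
    xyz = np.asarray(xyz, dtype=float)
    if len(xyz) == 0:
        raise LatticeError("sasa: empty atom set")
    radii = atom_radii(elements, default=default_radius) + probe
    unit = sphere_points(n_points) @ _canonical_frame(xyz).T
    tree = cKDTree(xyz)
    max_r = radii.max()
    areas = np.empty(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + radii[i] * unit
        nb = tree.query_ball_point(xyz[i], radii[i] + max_r)
        nb = [j for j in nb if j != i]
        if nb:
            d = np.linalg.norm(pts[:, None, :] - xyz[nb][None, :, :], axis=2)
            buried = (d < radii[nb][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(per_atom=areas, probe=probe, n_points=n_points)


def sasa_structure(s: Structure, probe: float = 1.4, n_points: int = 960,
                   **kw) -> SasaResult:
    return sasa(s.coords(heavy_only=True), s.elements(heavy_only=True),
                probe=probe, n_points=n_points, **kw)


@dataclass
class InterfaceArea:
    """Buried area between two selections (single-interface convention)."""

    sel_a: str
    sel_b: str
    area: float
    op: SymOp | None = None
    shift: tuple[int, int, int] = (0, 0, 0)

    @property
    def op_label(self) -> str:
        if self.op is None or (self.op.is_identity and self.shift == (0, 0, 0)):
            return "x,y,z"
        return self.op.triplet()


def _polymer_selection(s: Structure, chain_id: str, *,
                       include_hetero: bool = False) -> Structure:
    res = [r for r in s.residues if r.chain_id == chain_id
           and (include_hetero or (r.is_amino_acid and not r.is_water))]
    return Structure(res, cell=s.cell, space_group=s.space_group, id=s.id)


def interface_area(s: Structure, sel_a: str, sel_b: str, *,
                   op: SymOp | None = None,
                   shift: tuple[int, int, int] = (0, 0, 0),
                   probe: float = 1.4, n_points: int = 960,
                   include_hetero: bool = False) -> InterfaceArea:
    """Buried interface area between chain ``sel_a`` and chain ``sel_b``.

    If ``op``/``shift`` are given, ``sel_b`` is taken from that symmetry mate
    (cell and space group required).  Selections must be disjoint unless an
    operator separates them.
    """
    a = _polymer_selection(s, sel_a, include_hetero=include_hetero)
    b = _polymer_selection(s, sel_b, include_hetero=include_hetero)
    if not a.residues or not b.residues:
        raise LatticeError(f"empty selection: {sel_a!r} or {sel_b!r}")
    if sel_a == sel_b and (op is None or (op.is_identity and shift == (0, 0, 0))):
        raise LatticeError("selections are identical and no operator separates them")
    xa, ea = a.coords(), a.elements()
    xb, eb = b.coords(), b.elements()
    if op is not None and not (op.is_identity and shift == (0, 0, 0)):
        xb = apply_symop(op, shift, (s.cell, xb))
    sa = sasa(xa, ea, probe, n_points).total
    sb = sasa(xb, eb, probe, n_points).total
    sab = sasa(np.vstack([xa, xb]), list(ea) + list(eb), probe, n_points).total
    buried = max(0.0, (sa + sb - sab) / 2.0)
    return InterfaceArea(sel_a=sel_a, sel_b=sel_b, area=buried,
                         op=op, shift=shift)


def crystal_contact_table(s: Structure, cutoff: float = 5.0, *,
                          probe: float = 1.4, n_points: int = 960,
                          include_hetero: bool = False,
                          min_area: float = 1e-6) -> list[InterfaceArea]:
    """Interface areas for every chain pair, in-cell and across symmetry mates.

    One row per (chain pair, operator) with positive buried area; contacts
    that bury nothing are omitted.  Rows are keyed by the operator's canonical
    triplet string and lattice shift.
    """
    if s.cell is None or s.space_group is None:
        raise LatticeError("crystal_contact_table needs cell and space group")
    chains = [c for c in s.chain_ids
              if _polymer_selection(s, c, include_hetero=include_hetero).residues]
    rows: list[InterfaceArea] = []
    # identity contacts between distinct chains in the asymmetric unit
    for i, ca in enumerate(chains):
        for cb in chains[i + 1:]:
            row = interface_area(s, ca, cb, probe=probe, n_points=n_points,
                                 include_hetero=include_hetero)
            if row.area > min_area:
                rows.append(row)
    # contacts to symmetry mates
    polymer = Structure([r for ch in chains
                         for r in _polymer_selection(
                             s, ch, include_hetero=include_hetero).residues],
                        cell=s.cell, space_group=s.space_group, id=s.id)
    for nb in expand_neighbors(polymer, cutoff):
        for ca in chains:
            for cb in chains:
                row = interface_area(s, ca, cb, op=nb.op, shift=nb.shift,
                                     probe=probe, n_points=n_points,
                                     include_hetero=include_hetero)
                if row.area > min_area:
                    rows.append(row)
    return rows
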