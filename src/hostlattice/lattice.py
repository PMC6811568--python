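"""Crystallographic frame math, space-group operators and Matthews screening.

The crystal frame is handled in the standard crystallographic convention:
``a`` along Cartesian x, ``b`` in the xy-plane.  Symmetry operators act on
fractional coordinates as ``x' = R x + t``; translations are kept
*un-normalised* (the lattice-shift part is retained explicitly), so that two
operators sharing a rotation part but differing by a whole lattice translation
remain distinguishable — exactly the distinction a crystal-packing table needs
when it lists contacts to different unit-cell neighbours.

Host screening follows the Matthews-coefficient logic: a lattice is a viable
host for guest display when its volume per dalton (V_M, Å³/Da) is large (big
solvent channels) while it still diffracts to high resolution.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroup",
    "MatthewsResult",
    "HostCandidate",
    "Neighbor",
    "cell_volume",
    "frac_cart_transform",
    "parse_symop",
    "spacegroup_ops",
    "apply_symop",
    "expand_neighbors",
    "matthews",
    "solvent_fraction",
    "screen_hosts",
    "load_candidates",
    "reference_host_table",
]

# Matthews' specific-volume constant: with the classic partial specific volume
# v-bar = 0.74 cm^3/g, solvent fraction = 1 - 1.66*0.74 / V_M = 1 - 1.2284/V_M.
PROTEIN_PARTIAL_SPECIFIC_VOLUME = 0.74  # cm^3/g


class LatticeError(ValueError):
    """Invalid crystallographic input (degenerate cell, bad operator, ...)."""


# --------------------------------------------------------------------------
# Unit cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise LatticeError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise LatticeError(f"cell angles must be in (0, 180): {self}")
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise LatticeError(f"degenerate cell (metric not positive-definite): {self}")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return cell_volume(self)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.parameters)


def cell_volume(cell: UnitCell) -> float:
    """Triclinic cell volume in Å³.

    V = abc sqrt(1 - cos²α - cos²β - cos²γ + 2 cosα cosβ cosγ)
    """
    ca, cb, cg = (math.cos(math.radians(x))
                  for x in (cell.alpha, cell.beta, cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0.0:
        raise LatticeError(f"degenerate cell: {cell}")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def frac_cart_transform(cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonalisation and fractionalisation matrices ``(orth, frac)``.

    ``orth @ x_frac`` gives Cartesian Å; ``frac`` is its inverse.  Standard
    convention: a along x, b in the xy-plane.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (math.cos(math.radians(x))
                  for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    v = cell_volume(cell)
    orth = np.array([
        [a, b * cg, c * cb],
        [0.0, b * sg, c * (ca - cb * cg) / sg],
        [0.0, 0.0, v / (a * b * sg)],
    ])
    frac = np.linalg.inv(orth)
    return orth, frac


# --------------------------------------------------------------------------
# Symmetry operators
# --------------------------------------------------------------------------

def _normalise_triplet(text: str) -> str:
    # tolerate unicode minus/dashes and stray whitespace as printed in tables
    return (text.replace("−", "-").replace("–", "-")
                .replace("—", "-").replace(" ", ""))


@dataclass(frozen=True)
class SymOp:
    """Fractional-basis symmetry operator ``x' = rot @ x + trans``.

    ``rot`` is an integer 3×3 matrix; ``trans`` holds exact rationals so that
    the lattice-shift part (e.g. the "-1" in "-y, x-y-1, z-1/3") survives
    round-trips instead of being wrapped mod 1.
    """

    rot: tuple[tuple[int, int, int], ...]
    trans: tuple[Fraction, Fraction, Fraction]

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)),
                   (Fraction(0), Fraction(0), Fraction(0)))

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymOp":
        den = op.DEN
        rot = tuple(tuple(v // den for v in row) for row in op.rot)
        for row, irow in zip(op.rot, rot):
            for v, iv in zip(row, irow):
                if iv * den != v:
                    raise LatticeError(f"non-integer rotation part in {op.triplet()}")
        trans = tuple(Fraction(t, den) for t in op.tran)
        return cls(rot, trans)  # type: ignore[arg-type]

    def to_gemmi(self) -> gemmi.Op:
        den = gemmi.Op().DEN
        op = gemmi.Op()
        op.rot = [[v * den for v in row] for row in self.rot]
        op.tran = [int(t * den) for t in self.trans]
        return op

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.trans])

    @property
    def is_identity(self) -> bool:
        return (self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1))
                and all(t == 0 for t in self.trans))

    def triplet(self) -> str:
        return self.to_gemmi().triplet()

    def normalized(self) -> "SymOp":
        """Equivalent operator with translations wrapped into [0, 1)."""
        return SymOp(self.rot, tuple(t % 1 for t in self.trans))

    def __mul__(self, other: "SymOp") -> "SymOp":
        """Composition: ``(self * other)(x) = self(other(x))``."""
        r1, r2 = np.array(self.rot, dtype=object), np.array(other.rot, dtype=object)
        rot = tuple(tuple(int(v) for v in row) for row in (r1 @ r2))
        t2 = np.array(other.trans, dtype=object)
        trans = tuple((r1 @ t2)[i] + self.trans[i] for i in range(3))
        return SymOp(rot, trans)  # type: ignore[arg-type]

    def inverse(self) -> "SymOp":
        r = np.array(self.rot, dtype=object)
        det = int(round(np.linalg.det(r.astype(float))))
        if det not in (1, -1):
            raise LatticeError(f"operator rotation not unimodular: {self.triplet()}")
        inv = np.round(np.linalg.inv(r.astype(float)) * 1).astype(int)
        trans = tuple(-sum(int(inv[i, j]) * self.trans[j] for j in range(3))
                      for i in range(3))
        rot = tuple(tuple(int(v) for v in row) for row in inv)
        return SymOp(rot, trans)  # type: ignore[arg-type]

    def same_rotation(self, other: "SymOp") -> bool:
        return self.rot == other.rot

    def lattice_shift_from(self, other: "SymOp") -> tuple[Fraction, ...] | None:
        """If self and other differ only by a whole lattice translation,
        return that integer shift; otherwise None."""
        if not self.same_rotation(other):
            return None
        diff = tuple(a - b for a, b in zip(self.trans, other.trans))
        if all(d.denominator == 1 for d in diff):
            return diff
        return None


def parse_symop(text: str) -> SymOp:
    """Parse a coordinate-triplet symmetry operator such as "-y, x-y-1, z-1/3".

    Unicode minus signs (as typeset in journal tables) are accepted.  The
    translation is stored exactly as written — "z-1/3" and "z+2/3" parse to
    operators that differ by a lattice translation but are not identical.
    """
    cleaned = _normalise_triplet(text)
    try:
        op = gemmi.Op(cleaned)
    except Exception as exc:  # gemmi raises RuntimeError with the bad token
        raise LatticeError(f"cannot parse symmetry triplet {text!r}: {exc}") from exc
    return SymOp.from_gemmi(op)


@dataclass(frozen=True)
class SpaceGroup:
    """Hermann–Mauguin symbol plus the full operator list (identity first)."""

    hm_symbol: str
    ops: tuple[SymOp, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.ops)

    def is_closed(self) -> bool:
        """Group closure modulo lattice translations."""
        normalized = {op.normalized() for op in self.ops}
        for p in self.ops:
            for q in self.ops:
                if (p * q).normalized() not in normalized:
                    return False
        return True


def spacegroup_ops(hm_symbol: str) -> SpaceGroup:
    """Full coset list for a space group given its Hermann–Mauguin symbol.

    Accepts both spaced ("P 65") and condensed ("P65") spellings.
    """
    sg = gemmi.find_spacegroup_by_name(hm_symbol)
    if sg is None:
        raise LatticeError(
            f"unsupported space-group symbol {hm_symbol!r}; use a Hermann-Mauguin "
            "symbol such as 'P 1', 'P 21', 'P 65', 'C 2', 'P 21 21 21'")
    ops = tuple(SymOp.from_gemmi(op) for op in sg.operations())
    # put identity first, keep gemmi's order otherwise
    idents = [o for o in ops if o.is_identity]
    rest = [o for o in ops if not o.is_identity]
    return SpaceGroup(sg.hm, tuple(idents + rest))


# --------------------------------------------------------------------------
# Symmetry expansion
# --------------------------------------------------------------------------

def apply_symop(op: SymOp, shift: Sequence[int], s) -> np.ndarray:
    """Cartesian coordinates of the symmetry mate ``orth(R frac(x) + t + shift)``.

    ``s`` is a Structure (needs ``cell`` and a ``coords()`` method) or a tuple
    ``(cell, coords)``.
    """
    if hasattr(s, "cell"):
        cell, xyz = s.cell, s.coords()
    else:
        cell, xyz = s
    if cell is None:
        raise LatticeError("structure has no unit cell; cannot apply symmetry")
    orth, frac = frac_cart_transform(cell)
    fx = xyz @ frac.T
    fx = fx @ op.rot_array.T + op.trans_array + np.asarray(shift, dtype=float)
    return fx @ orth.T


@dataclass(frozen=True)
class Neighbor:
    """A symmetry mate in contact with the reference copy."""

    op_index: int
    op: SymOp
    shift: tuple[int, int, int]
    coords: np.ndarray
    min_dist: float

    def label(self) -> str:
        s = "+".join(str(v) for v in self.shift)
        return f"{self.op.triplet()} shift=({s})"


def expand_neighbors(s, cutoff: float, *, shift_range: int = 2,
                     force: bool = False) -> list[Neighbor]:
    """All symmetry mates with any atom within ``cutoff`` Å of the reference.

    The identity operator with zero shift (the reference itself) is excluded;
    pure lattice translations count as mates.  Deterministic order: by operator
    index in the group's coset list, then by shift tuple.
    """
    if cutoff <= 0:
        raise LatticeError("cutoff must be positive")
    if s.cell is None or s.space_group is None:
        raise LatticeError("structure needs cell and space group for expansion")
    cell = s.cell
    diag = math.sqrt(cell.a ** 2 + cell.b ** 2 + cell.c ** 2)
    if cutoff > 2 * diag and not force:
        raise LatticeError(
            f"cutoff {cutoff} Å exceeds twice the cell diagonal ({diag:.1f} Å); "
            "pass force=True for a runaway expansion")
    xyz = s.coords()
    if len(xyz) == 0:
        return []
    orth, frac = frac_cart_transform(cell)
    fx = xyz @ frac.T
    tree = cKDTree(xyz)
    out: list[Neighbor] = []
    shifts = range(-shift_range, shift_range + 1)
    ref_lo, ref_hi = xyz.min(axis=0), xyz.max(axis=0)
    for i, op in enumerate(s.space_group.ops):
        base = fx @ op.rot_array.T + op.trans_array
        for si in shifts:
            for sj in shifts:
                for sk in shifts:
                    if i == 0 and op.is_identity and si == sj == sk == 0:
                        continue
                    mate = (base + np.array([si, sj, sk], dtype=float)) @ orth.T
                    # bounding-box rejection before the pair search
                    lo, hi = mate.min(axis=0), mate.max(axis=0)
                    gap = np.maximum(ref_lo - hi, lo - ref_hi)
                    if np.linalg.norm(np.maximum(gap, 0.0)) > cutoff:
                        continue
                    d, _ = tree.query(mate, k=1)
                    dmin = float(d.min())
                    if dmin <= cutoff:
                        out.append(Neighbor(i, op, (si, sj, sk), mate, dmin))
    out.sort(key=lambda nb: (nb.op_index, nb.shift))
    return out


# --------------------------------------------------------------------------
# Matthews screening
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MatthewsResult:
    v_cell: float       # Å³
    z_total: int        # molecules per cell
    mw: float           # Da
    v_m: float          # Å³/Da
    solvent_frac: float  # [0, 1]


def solvent_fraction(v_m: float,
                     v_bar: float = PROTEIN_PARTIAL_SPECIFIC_VOLUME) -> float:
    """Solvent fraction of a crystal from its Matthews coefficient.

    ``1 - 1.66 v_bar / V_M``, clipped to [0, 1]; with the classic
    v_bar = 0.74 cm³/g this is ``1 - 1.2284 / V_M``.
    """
    if v_m <= 0:
        raise LatticeError("V_M must be positive")
    return min(1.0, max(0.0, 1.0 - 1.66 * v_bar / v_m))


def matthews(cell: UnitCell, sg: SpaceGroup | str, mw: float,
             n_per_asu: int = 1,
             v_bar: float = PROTEIN_PARTIAL_SPECIFIC_VOLUME) -> MatthewsResult:
    """Matthews coefficient and solvent fraction for a crystal form.

    ``z_total`` is the space-group multiplicity times the number of molecules
    per asymmetric unit; ``v_m = V_cell / (z_total * MW)``.
    """
    if mw <= 0:
        raise LatticeError("molecular weight must be positive")
    if n_per_asu < 1:
        raise LatticeError("n_per_asu must be >= 1")
    if isinstance(sg, str):
        sg = spacegroup_ops(sg)
    v = cell_volume(cell)
    z = sg.multiplicity * n_per_asu
    v_m = v / (z * mw)
    return MatthewsResult(v, z, mw, v_m, solvent_fraction(v_m, v_bar))


@dataclass(frozen=True)
class HostCandidate:
    """One row of a host-lattice candidate table."""

    pdb_id: str
    v_m: float          # Å³/Da
    resolution: float   # Å
    name: str = ""

    def __post_init__(self) -> None:
        if self.v_m <= 0 or self.resolution <= 0:
            raise LatticeError(f"invalid candidate row: {self}")


def screen_hosts(candidates: Iterable[HostCandidate],
                 min_vm: float = 4.3, max_res: float = 2.0) -> list[HostCandidate]:
    """Filter and rank host-lattice candidates.

    Keeps entries with V_M >= ``min_vm`` and resolution <= ``max_res``; ranks
    by V_M descending, breaking ties by resolution ascending then PDB id.  The
    defaults are the tightest bounds that admit every reference host (large
    solvent channels, still high resolution).
    """
    kept = [c for c in candidates if c.v_m >= min_vm and c.resolution <= max_res]
    kept.sort(key=lambda c: (-c.v_m, c.resolution, c.pdb_id))
    return kept


def load_candidates(path_or_buffer) -> list[HostCandidate]:
    """Read a candidate table from CSV.

    Requires columns ``pdb_id`` and ``resolution``; V_M is taken from a
    ``v_m`` column if present, otherwise computed from
    ``a,b,c,alpha,beta,gamma,sg,mw,n_asu``.
    """
    if hasattr(path_or_buffer, "read"):
        rows = list(csv.DictReader(path_or_buffer))
    else:
        with open(path_or_buffer, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        if row.get("v_m"):
            vm = float(row["v_m"])
        else:
            cell = UnitCell(*(float(row[k]) for k in
                              ("a", "b", "c", "alpha", "beta", "gamma")))
            res = matthews(cell, row["sg"], float(row["mw"]),
                           int(row.get("n_asu", 1) or 1))
            vm = res.v_m
        out.append(HostCandidate(pdb_id=row["pdb_id"], v_m=vm,
                                 resolution=float(row["resolution"]),
                                 name=row.get("name", "")))
    return out


def reference_host_table() -> list[HostCandidate]:
    """The published table of high-solvent, high-resolution host candidates."""
    with resources.files("hostlattice.data").joinpath(
            "host_candidates.csv").open("r", newline="") as fh:
        return load_candidates(fh)
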