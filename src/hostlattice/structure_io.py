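"""Macromolecular structure model, PDB/mmCIF input-output and toy fixtures.

The in-memory model is a flat, ordered list of residues, each holding its
atoms, plus the crystallographic metadata (unit cell, space group) that the
rest of the toolkit needs.  Author residue numbering is authoritative
throughout — engineered-mutation sites are cited by author numbers in the
literature, so that is the numbering every scan and report uses.

Parsing and writing are delegated to gemmi, which handles fixed-column PDB
(including hybrid-36 encoding once atom serials exceed 99999 or residue
numbers exceed 9999) as well as mmCIF.  By default alternate conformations
are collapsed to the highest-occupancy conformer and hydrogens are kept but
flagged, so geometric computations can exclude them uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import gemmi
import numpy as np

from .lattice import LatticeError, SpaceGroup, UnitCell, spacegroup_ops

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureParseError",
    "read_structure",
    "read_structure_string",
    "write_structure",
    "structure_to_string",
    "make_toy_crystal",
    "read_fasta_mw",
    "STANDARD_AMINO_ACIDS",
    "WATER_NAMES",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine counts as protein in deposition censuses
}
WATER_NAMES = {"HOH", "WAT", "DOD"}

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class StructureParseError(ValueError):
    """Malformed structure file; message names the offending record."""


@dataclass
class Atom:
    """A single atom site."""

    serial: int
    name: str
    element: str
    xyz: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"atom {self.name}: xyz must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.b_iso < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue: identity by (chain_id, seq_id, ins_code), author numbering."""

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    ins_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.ins_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS


@dataclass
class Structure:
    """Ordered residues plus optional crystallographic frame."""

    residues: list[Residue] = field(default_factory=list)
    cell: UnitCell | None = None
    space_group: SpaceGroup | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.space_group is not None and self.cell is None:
            raise ValueError("space group present but no unit cell")

    # -- iteration helpers -------------------------------------------------

    def iter_atoms(self, *, heavy_only: bool = False
                   ) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                if heavy_only and atom.is_hydrogen:
                    continue
                yield res, atom

    def coords(self, *, heavy_only: bool = True) -> np.ndarray:
        """Coordinate array (n, 3); hydrogens excluded by default."""
        pts = [a.xyz for _, a in self.iter_atoms(heavy_only=heavy_only)]
        if not pts:
            return np.zeros((0, 3))
        return np.array(pts)

    def elements(self, *, heavy_only: bool = True) -> list[str]:
        return [a.element for _, a in self.iter_atoms(heavy_only=heavy_only)]

    def count_atoms(self, *, heavy_only: bool = False) -> int:
        return sum(1 for _ in self.iter_atoms(heavy_only=heavy_only))

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def select_chains(self, chain_ids: Sequence[str] | str) -> "Structure":
        if isinstance(chain_ids, str):
            chain_ids = [chain_ids]
        wanted = set(chain_ids)
        return Structure([r for r in self.residues if r.chain_id in wanted],
                         cell=self.cell, space_group=self.space_group,
                         id=self.id)

    def select_range(self, chain_id: str, start: int, end: int) -> "Structure":
        res = [r for r in self.residues
               if r.chain_id == chain_id and start <= r.seq_id <= end]
        return Structure(res, cell=self.cell, space_group=self.space_group,
                         id=self.id)

    def residue(self, chain_id: str, seq_id: int, ins_code: str = ""
                ) -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, seq_id, ins_code):
                return r
        return None

    def with_coords(self, xyz: np.ndarray, *, heavy_only: bool = True
                    ) -> "Structure":
        """Copy of the structure with coordinates replaced in atom order."""
        new = Structure([Residue(r.chain_id, r.seq_id, r.res_name,
                                 [replace(a) for a in r.atoms], r.ins_code)
                         for r in self.residues],
                        cell=self.cell, space_group=self.space_group, id=self.id)
        k = 0
        for _, atom in new.iter_atoms(heavy_only=heavy_only):
            atom.xyz = np.asarray(xyz[k], dtype=float)
            k += 1
        if k != len(xyz):
            raise ValueError(f"coordinate count mismatch: {len(xyz)} given, {k} needed")
        return new


# --------------------------------------------------------------------------
# gemmi conversion
# --------------------------------------------------------------------------

def _collapse_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties break alphabetically."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if (prev is None or atom.occ > prev.occ
                or (atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~"))):
            best[atom.name] = atom
    # preserve file order of first appearance
    seen, ordered = set(), []
    for atom in residue:
        if atom.name not in seen:
            seen.add(atom.name)
            ordered.append(best[atom.name])
    return ordered


def _from_gemmi(st: gemmi.Structure, *, altloc: str = "collapse") -> Structure:
    cell = None
    if st.cell and st.cell.a > 0 and not (
            st.cell.a == st.cell.b == st.cell.c == 1.0
            and st.cell.alpha == st.cell.beta == st.cell.gamma == 90.0):
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = None
    if cell is not None and st.spacegroup_hm:
        try:
            sg = spacegroup_ops(st.spacegroup_hm)
        except LatticeError:
            sg = None
    residues: list[Residue] = []
    if len(st) == 0:
        return Structure([], cell=cell, space_group=sg, id=st.name)
    model = st[0]
    for chain in model:
        for gres in chain:
            atoms_src = (_collapse_altlocs(gres) if altloc == "collapse"
                         else list(gres))
            atoms = [Atom(serial=a.serial, name=a.name,
                          element=a.element.name or "X",
                          xyz=np.array([a.pos.x, a.pos.y, a.pos.z]),
                          alt_loc=(a.altloc or ""),
                          occupancy=min(max(a.occ, 0.0), 1.0),
                          b_iso=max(a.b_iso, 0.0))
                     for a in atoms_src]
            residues.append(Residue(chain_id=chain.name,
                                    seq_id=gres.seqid.num,
                                    res_name=gres.name,
                                    atoms=atoms,
                                    ins_code=(gres.seqid.icode or "").strip()))
    return Structure(residues, cell=cell, space_group=sg, id=st.name)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id or "model"
    if s.cell is not None:
        st.cell = s.cell.to_gemmi()
    if s.space_group is not None:
        st.spacegroup_hm = s.space_group.hm_symbol
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in s.residues:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_id, res.ins_code or " ")
        for atom in res.atoms:
            serial += 1
            ga = gemmi.Atom()
            ga.serial = serial
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.altloc = atom.alt_loc or "\0"
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_iso
            ga.pos = gemmi.Position(*atom.xyz)
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


# --------------------------------------------------------------------------
# read / write
# --------------------------------------------------------------------------

Format = Literal["pdb", "mmcif", "auto"]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="ignore")[:2048]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def read_structure(path, format: Format = "auto", *,
                   altloc: str = "collapse") -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    ``altloc='collapse'`` (default) keeps the highest-occupancy conformer per
    atom name; ``altloc='raw'`` keeps every alternate location.  A missing
    unit cell is not an error — the structure simply has ``cell=None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc
    st.setup_entities()
    out = _from_gemmi(st, altloc=altloc)
    if not out.id or out.id == "model":
        out.id = path.stem
    return out


def read_structure_string(text: str, format: Literal["pdb", "mmcif"] = "pdb",
                          *, altloc: str = "collapse", id: str = "") -> Structure:
    """Parse structure text (PDB records or an mmCIF block)."""
    try:
        if format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(str(exc)) from exc
    out = _from_gemmi(st, altloc=altloc)
    if id:
        out.id = id
    return out


def write_structure(s: Structure, path, format: Format = "auto") -> None:
    """Write a Structure as PDB or mmCIF.

    Round-trips preserve atom count, names, author numbering, occupancy,
    B-factors, cell and space group; PDB coordinates carry three decimals.
    Structures too large for fixed PDB columns are written with hybrid-36
    serials (mmCIF is lossless and preferred for very large models).
    """
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    path.write_text(structure_to_string(s, "mmcif" if fmt == "mmcif" else "pdb"))


def structure_to_string(s: Structure, format: Literal["pdb", "mmcif"] = "pdb") -> str:
    st = _to_gemmi(s)
    if format == "mmcif":
        return st.make_mmcif_document().as_string()
    return st.make_pdb_string()


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

# local backbone geometry for a generic extended/compact chain fixture
_BB_OFFSETS = {
    # placed relative to CA in a local orthonormal frame (t: chain direction,
    # n: normal, b: binormal); bond lengths near ideal values
    "N": (-1.20, 0.60, 0.45),
    "C": (1.25, 0.55, -0.45),
    "O": (1.55, 1.75, -0.55),
    "CB": (-0.15, -1.20, 0.95),
}


def _chain_from_ca_trace(ca: np.ndarray, chain_id: str = "A",
                         start_seq: int = 1, b_iso: float = 20.0
                         ) -> list[Residue]:
    """Poly-alanine residues around a CA trace, with a simple local frame."""
    n = len(ca)
    residues = []
    serial = 0
    for i in range(n):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[min(i + 1, n - 1)] - ca[i])
        next_ca = ca[i + 1] if i < n - 1 else ca[i] + (ca[i] - ca[max(i - 1, 0)])
        t = next_ca - prev_ca
        tn = np.linalg.norm(t)
        t = t / tn if tn > 1e-9 else np.array([1.0, 0.0, 0.0])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, t)) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        b = np.cross(t, ref)
        b /= np.linalg.norm(b)
        nvec = np.cross(b, t)
        frame = np.stack([t, nvec, b], axis=1)
        atoms = []
        for name, off in (("N", _BB_OFFSETS["N"]), ("CA", (0.0, 0.0, 0.0)),
                          ("C", _BB_OFFSETS["C"]), ("O", _BB_OFFSETS["O"]),
                          ("CB", _BB_OFFSETS["CB"])):
            serial += 1
            pos = ca[i] + frame @ np.array(off)
            element = name[0]
            atoms.append(Atom(serial=serial, name=name, element=element,
                              xyz=pos, b_iso=b_iso))
        residues.append(Residue(chain_id=chain_id, seq_id=start_seq + i,
                                res_name="ALA", atoms=atoms))
    return residues


def _self_avoiding_ca_walk(n_res: int, rng: np.random.Generator,
                           min_sep: float = 3.6) -> np.ndarray:
    """Compact CA random walk with 3.8 Å steps and no non-bonded pair < min_sep."""
    for _ in range(200):
        pts = [np.zeros(3)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        ok = True
        for _ in range(n_res - 1):
            placed = False
            for _ in range(60):
                perturb = rng.normal(scale=0.7, size=3)
                cand_dir = direction + perturb
                cand_dir /= np.linalg.norm(cand_dir)
                cand = pts[-1] + 3.8 * cand_dir
                if len(pts) < 2 or min(np.linalg.norm(cand - p)
                                       for p in pts[:-1]) >= min_sep:
                    pts.append(cand)
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("could not build a self-avoiding CA walk")


_CRYSTAL_SYSTEM_CHECKS = {
    # family letter of the HM symbol -> constraint on (a,b,c,alpha,beta,gamma)
    "hexagonal": lambda c: math.isclose(c.a, c.b, rel_tol=1e-9)
    and math.isclose(c.alpha, 90) and math.isclose(c.beta, 90)
    and math.isclose(c.gamma, 120),
    "tetragonal": lambda c: math.isclose(c.a, c.b, rel_tol=1e-9)
    and all(math.isclose(x, 90) for x in (c.alpha, c.beta, c.gamma)),
    "orthorhombic": lambda c: all(math.isclose(x, 90)
                                  for x in (c.alpha, c.beta, c.gamma)),
    "monoclinic": lambda c: math.isclose(c.alpha, 90) and math.isclose(c.gamma, 90),
    "triclinic": lambda c: True,
    "cubic": lambda c: math.isclose(c.a, c.b, rel_tol=1e-9)
    and math.isclose(c.b, c.c, rel_tol=1e-9)
    and all(math.isclose(x, 90) for x in (c.alpha, c.beta, c.gamma)),
    "trigonal": lambda c: math.isclose(c.a, c.b, rel_tol=1e-9)
    and math.isclose(c.alpha, 90) and math.isclose(c.beta, 90)
    and math.isclose(c.gamma, 120),
}


def _check_cell_vs_system(sg_symbol: str, cell: UnitCell) -> None:
    sg = gemmi.find_spacegroup_by_name(sg_symbol)
    if sg is None:
        raise LatticeError(f"unsupported space group {sg_symbol!r}")
    system = sg.crystal_system_str()
    check = _CRYSTAL_SYSTEM_CHECKS.get(system)
    if check is not None and not check(cell):
        raise LatticeError(
            f"cell {cell.parameters} violates {system} constraints of {sg.hm}")


def make_toy_crystal(space_group: str, cell: UnitCell, n_res: int,
                     seed: int) -> Structure:
    """Deterministic toy crystal: one poly-alanine chain in the asymmetric unit.

    The chain is a compact self-avoiding walk placed off the symmetry axes so
    that, for the sizes used in tests, neither the chain itself nor its
    symmetry mates clash below 2.0 Å.  Same seed, same structure; different
    seed, different coordinates with the same invariants.
    """
    _check_cell_vs_system(space_group, cell)
    sg = spacegroup_ops(space_group)
    from .lattice import frac_cart_transform  # local import keeps cycle-free
    orth, _ = frac_cart_transform(cell)
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        ca = _self_avoiding_ca_walk(n_res, rng)
        ca -= ca.mean(axis=0)
        # anchor the chain at a general position, away from rotation axes
        anchor = orth @ np.array([0.32, 0.12, 0.23])
        residues = _chain_from_ca_trace(ca + anchor)
        s = Structure(residues, cell=cell, space_group=sg,
                      id=f"toy-{space_group.replace(' ', '')}-{seed}")
        if _toy_packs_ok(s):
            return s
    raise RuntimeError(
        f"no clash-free placement found for {n_res} residues in {space_group} "
        f"cell {cell.parameters}; use a larger cell or fewer residues")


def _toy_packs_ok(s: Structure, min_dist: float = 2.0) -> bool:
    from .lattice import expand_neighbors
    xyz = s.coords()
    # self-clash: non-bonded atoms below threshold
    from scipy.spatial import cKDTree
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(min_dist)
    atoms = [(ri, a) for ri, res in enumerate(s.residues)
             for a in res.atoms if not a.is_hydrogen]
    for i, j in pairs:
        (ri, _), (rj, _) = atoms[i], atoms[j]
        if abs(ri - rj) > 1:  # tolerate within-residue and peptide-bond contacts
            return False
    neighbors = expand_neighbors(s, cutoff=min_dist)
    return len(neighbors) == 0


# --------------------------------------------------------------------------
# sequence molecular weight
# --------------------------------------------------------------------------

def read_fasta_mw(path) -> dict[str, float]:
    """Average molecular weight (Da) of each protein sequence in a FASTA file."""
    from Bio import SeqIO
    from Bio.SeqUtils import molecular_weight
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace("*", "").replace("X", "")
        out[rec.id] = molecular_weight(seq, seq_type="protein")
    return out
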