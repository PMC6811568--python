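"""Rigid shared-helix fusion, rotational enumeration and cavity sizing.

A binder domain is rigidly attached to a host scaffold by merging the host's
C-terminal α-helix with the binder's N-terminal helix into one continuous
helix.  Inserting ``k`` extra residues into the shared helix advances the
binder by ``k × rise`` along the helix axis and rotates it by ``k × twist``
about it — an α-helix (3.6 residues/turn) turns ~100° per residue — so
stepping ``k`` enumerates binder orientations around the helix axis without
touching the internal geometry of either domain.  Each orientation is scored
by counting steric clashes against the host and its crystal lattice, and the
space available to a guest at the binder paratope is sized as the largest
sphere that fits the lattice channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .analyze import kabsch
from .contacts import atom_radii
from .lattice import LatticeError, expand_neighbors
from .structure_io import Atom, Residue, Structure

__all__ = [
    "HelixParams",
    "HelixAxis",
    "FusionModel",
    "CavityEstimate",
    "build_ideal_helix",
    "fit_helix_axis",
    "shared_helix_fuse",
    "clash_score",
    "enumerate_rotations",
    "cavity_radius",
]


@dataclass(frozen=True)
class HelixParams:
    """Ideal α-helix geometry: 1.5 Å rise and 100°/residue (3.6 res/turn)."""

    rise: float = 1.5        # Å per residue
    twist: float = 100.0     # degrees per residue
    ca_radius: float = 2.3   # Å

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0.0 < self.twist <= 180.0:
            raise ValueError("twist must be in (0, 180]")


# Backbone-atom offsets relative to CA in the local cylindrical frame
# (radial, tangential, axial), frozen from a dihedral-built ideal helix
# (phi = -57.8°, psi = -47.0°); they make every residue congruent, so the
# built helix has exact screw symmetry.
_LOCAL_OFFSETS = {
    "N": (-0.8923, -0.7037, -0.9134),
    "C": (-0.7863, 0.7588, 1.0638),
    "O": (-0.4681, 0.6806, 2.2504),
    "CB": (0.9034, 0.9556, -0.7821),
}


@dataclass(frozen=True)
class HelixAxis:
    """Fitted helix axis with per-residue rise/twist estimates.

    ``direction`` points from the N- to the C-terminal end of the fitted
    range.  ``non_helical`` is set when the CA trace does not wind a cylinder
    (straight or irregular segments).
    """

    origin: np.ndarray
    direction: np.ndarray
    rise: float
    twist: float       # degrees, signed (+ right-handed)
    radius: float
    residual: float    # rms radial deviation, Å
    non_helical: bool = False
    residue_range: tuple[str, int, int] | None = None


def _helix_ca(n: int, params: HelixParams) -> np.ndarray:
    k = np.arange(n, dtype=float)
    theta = np.radians(params.twist) * k
    return np.stack([params.ca_radius * np.cos(theta),
                     params.ca_radius * np.sin(theta),
                     params.rise * k], axis=1)


def build_ideal_helix(n: int, params: HelixParams = HelixParams(), *,
                      chain_id: str = "A", start_seq: int = 1,
                      b_iso: float = 20.0) -> Structure:
    """Ideal poly-alanine α-helix along +z with CA atoms on a cylinder.

    CA(i) sits at angle ``i × twist`` and height ``i × rise``; N, C, O and CB
    are placed by fixed offsets in the local cylindrical frame, so the helix
    is exactly screw-symmetric.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    ca = _helix_ca(n, params)
    theta = np.radians(params.twist) * np.arange(n)
    residues = []
    serial = 0
    for i in range(n):
        e_r = np.array([np.cos(theta[i]), np.sin(theta[i]), 0.0])
        e_t = np.array([-np.sin(theta[i]), np.cos(theta[i]), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        frame = np.stack([e_r, e_t, e_z], axis=1)
        atoms = []
        for name in ("N", "CA", "C", "O", "CB"):
            serial += 1
            off = np.zeros(3) if name == "CA" else np.array(_LOCAL_OFFSETS[name])
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              xyz=ca[i] + frame @ off, b_iso=b_iso))
        residues.append(Residue(chain_id=chain_id, seq_id=start_seq + i,
                                res_name="ALA", atoms=atoms))
    return Structure(residues)


def fit_helix_axis(ca: np.ndarray, *, residue_range=None,
                   residual_threshold: float = 0.25) -> HelixAxis:
    """Least-squares axis fit of a CA trace.

    The axis direction comes from cross products of successive second
    differences (exactly axial for an ideal helix); the radius and centre
    from an algebraic circle fit of the projected points; rise and twist are
    the mean axial advance and the mean turning angle.  ≥ 5 CA positions are
    required; traces whose radial spread exceeds ``residual_threshold`` (or
    that are essentially straight) are flagged ``non_helical``.
    """
    ca = np.asarray(ca, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or len(ca) < 5:
        raise ValueError("need >= 5 CA positions to fit a helix axis")
    d = np.diff(ca, axis=0)
    s = np.diff(d, axis=0)
    w = np.zeros(3)
    for i in range(len(s) - 1):
        w += np.cross(s[i], s[i + 1])
    norm = np.linalg.norm(w)
    step = np.linalg.norm(d, axis=1).mean()
    if norm < 1e-6 * max(step, 1.0) ** 2:
        # straight or planar-degenerate trace: no winding
        direction = ca[-1] - ca[0]
        direction = direction / max(np.linalg.norm(direction), 1e-12)
        return HelixAxis(origin=ca.mean(axis=0), direction=direction,
                         rise=float(step), twist=0.0, radius=0.0,
                         residual=float("inf"), non_helical=True,
                         residue_range=residue_range)
    w /= norm
    if np.dot(w, ca[-1] - ca[0]) < 0:
        w = -w
    # in-plane basis
    u = np.cross(w, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(u) < 0.1:
        u = np.cross(w, np.array([0.0, 1.0, 0.0]))
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    pts2 = np.stack([ca @ u, ca @ v], axis=1)
    a_mat = np.column_stack([2 * pts2, np.ones(len(pts2))])
    sol, *_ = np.linalg.lstsq(a_mat, (pts2 ** 2).sum(axis=1), rcond=None)
    centre2 = sol[:2]
    radius = float(np.sqrt(max(sol[2] + centre2 @ centre2, 0.0)))
    radial = pts2 - centre2
    radii = np.linalg.norm(radial, axis=1)
    residual = float(np.sqrt(((radii - radius) ** 2).mean()))
    z = ca @ w
    rise = float(np.diff(z).mean())
    angles = np.unwrap(np.arctan2(radial[:, 1], radial[:, 0]))
    twist = float(np.degrees(np.diff(angles).mean()))
    origin = centre2[0] * u + centre2[1] * v + z.mean() * w
    non_helical = residual > residual_threshold or radius < 0.5
    return HelixAxis(origin=origin, direction=w, rise=rise, twist=twist,
                     radius=radius, residual=residual,
                     non_helical=non_helical, residue_range=residue_range)


@dataclass
class FusionModel:
    """A host+binder model at one shared-helix extension length ``k``."""

    coords: Structure
    k_inserted: int
    rotation_deg: float          # binder rotation about the shared axis vs k=0
    twist: float                 # degrees per inserted residue (from the fit)
    axis_point: np.ndarray
    axis_direction: np.ndarray
    host_chain: str = "A"
    binder_chain: str = "B"
    extension_seqs: tuple[int, ...] = ()
    clash_count: int | None = None
    clash_pairs: list = field(default_factory=list)


def _anchor_cas(s: Structure, anchor: tuple[str, int, int]) -> np.ndarray:
    chain, start, end = anchor
    cas = []
    for res in s.residues:
        if res.chain_id == chain and start <= res.seq_id <= end:
            a = res.atom("CA")
            if a is not None:
                cas.append(a.xyz)
    if len(cas) < 5:
        raise ValueError(f"anchor {anchor} has {len(cas)} CA atoms; need >= 5")
    return np.array(cas)


def _rotation_about_axis(rot: np.ndarray, axis: np.ndarray) -> float:
    """Signed rotation angle (degrees) of a rotation matrix about a given axis."""
    from scipy.spatial.transform import Rotation
    rv = Rotation.from_matrix(rot).as_rotvec()
    return float(np.degrees(rv @ (axis / np.linalg.norm(axis))))


def shared_helix_fuse(host: Structure, host_anchor: tuple[str, int, int],
                      binder: Structure, binder_anchor: tuple[str, int, int],
                      k: int, *, window: int = 7,
                      params: HelixParams | None = None,
                      force: bool = False) -> FusionModel:
    """Fuse a binder onto a host through a shared helix extended by ``k`` residues.

    The host anchor helix (C-terminal, author-numbered range) is continued
    along its own fitted axis and phase by ``k`` ideal alanine residues; the
    binder is then rigid-body placed by superposing the first ``window``
    residues of its N-terminal anchor helix onto the next turn of the ideal
    continuation.  The binder's internal geometry is untouched.  Anchors that
    do not fit a helix raise unless ``force`` is set.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    host_ca = _anchor_cas(host, host_anchor)
    bind_ca = _anchor_cas(binder, binder_anchor)
    fit_h = fit_helix_axis(host_ca, residue_range=host_anchor)
    fit_b = fit_helix_axis(bind_ca, residue_range=binder_anchor)
    if (fit_h.non_helical or fit_b.non_helical) and not force:
        bad = "host" if fit_h.non_helical else "binder"
        raise ValueError(f"{bad} anchor is not helical "
                         f"(residual {max(fit_h.residual, fit_b.residual):.2f} Å); "
                         "pass force=True to fuse anyway")
    w = min(window, len(bind_ca))
    n_anchor = len(host_ca)
    ideal_params = params or HelixParams(rise=abs(fit_h.rise),
                                         twist=abs(fit_h.twist),
                                         ca_radius=fit_h.radius)
    m = n_anchor + k + w
    ideal = build_ideal_helix(m, ideal_params)
    ideal_ca = np.array([r.atom("CA").xyz for r in ideal.residues])
    # place the ideal helix onto the host anchor
    sup1 = kabsch(ideal_ca[:n_anchor], host_ca)
    placed_ca = sup1.apply(ideal_ca)
    axis_dir = sup1.rot @ np.array([0.0, 0.0, 1.0])
    axis_pt = sup1.apply(np.zeros((1, 3)))[0]
    # extension residues (alanine), numbering continues the host anchor chain
    chain, _, anchor_end = host_anchor
    ext_structs = []
    ext_seqs = []
    for j in range(k):
        res = ideal.residues[n_anchor + j]
        new = Residue(chain_id=chain, seq_id=anchor_end + 1 + j,
                      res_name="ALA",
                      atoms=[replace(a, xyz=sup1.apply(a.xyz[None, :])[0])
                             for a in res.atoms])
        ext_structs.append(new)
        ext_seqs.append(new.seq_id)
    # binder placement: its first w anchor CAs onto the continuation turn
    target = placed_ca[n_anchor + k:]
    sup2 = kabsch(bind_ca[:w], target)
    # reference orientation at k=0 for the rotation bookkeeping
    target0 = placed_ca[n_anchor:n_anchor + w]
    sup2_ref = kabsch(bind_ca[:w], target0)
    rel = sup2.rot @ sup2_ref.rot.T
    rotation = _rotation_about_axis(rel, axis_dir) % 360.0
    # rename binder chain if it collides with a host chain id
    used = set(host.chain_ids) | {chain}
    bchain = binder.chain_ids[0] if binder.chain_ids else "B"
    if bchain in used:
        for cand in "BCDEFGHIJKLMNOPQRSTUVWXYZab":
            if cand not in used:
                bchain = cand
                break
    binder_res = []
    for res in binder.residues:
        binder_res.append(Residue(
            chain_id=bchain, seq_id=res.seq_id, res_name=res.res_name,
            atoms=[replace(a, xyz=sup2.apply(a.xyz[None, :])[0])
                   for a in res.atoms],
            ins_code=res.ins_code))
    fused = Structure(list(host.residues) + ext_structs + binder_res,
                      cell=host.cell, space_group=host.space_group,
                      id=f"{host.id or 'host'}_fuse_k{k}")
    return FusionModel(coords=fused, k_inserted=k, rotation_deg=rotation,
                       twist=abs(fit_h.twist), axis_point=axis_pt,
                       axis_direction=axis_dir, host_chain=chain,
                       binder_chain=bchain, extension_seqs=tuple(ext_seqs))


def clash_score(model: FusionModel, lattice_context: Structure | None = None,
                cutoff: float = 3.0, *, junction_window: int = 4
                ) -> tuple[int, list]:
    """Count heavy-atom clashes of the moving part against the packed lattice.

    The moving part is the helix extension plus the binder; the environment is
    the host plus every symmetry mate of the whole fused model (from the
    lattice context, defaulting to the fused model's own cell).  Along the
    continuous fused helix (host anchor → extension → binder) residues within
    ``junction_window`` of each other are local helix neighbours — their
    backbone contacts, including the i,i+4 hydrogen bonds every α-helix has,
    are structure, not clashes — and are excluded.  Updates and returns
    ``(clash_count, clash_pairs)``.
    """
    s = model.coords
    ext_set = set(model.extension_seqs)
    # continuous residue index along the fused helix: anchor-chain residues
    # keep their author number (the extension continues it); binder residues
    # follow on after the extension
    binder_order = [r.seq_id for r in s.residues
                    if r.chain_id == model.binder_chain]
    ext_end = (max(ext_set) if ext_set
               else max((r.seq_id for r in s.residues
                         if r.chain_id == model.host_chain), default=0))
    cont_idx: dict[tuple[str, int], int] = {}
    for res in s.residues:
        if res.chain_id == model.host_chain:
            cont_idx[(res.chain_id, res.seq_id)] = res.seq_id
    for pos, seq in enumerate(binder_order, start=1):
        cont_idx[(model.binder_chain, seq)] = ext_end + pos
    moving, moving_meta = [], []
    env, env_meta = [], []
    for res in s.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            is_ext = res.chain_id == model.host_chain and res.seq_id in ext_set
            is_binder = res.chain_id == model.binder_chain
            if is_ext or is_binder:
                moving.append(atom.xyz)
                moving_meta.append((res.chain_id, res.seq_id, atom.name))
            else:
                env.append(atom.xyz)
                env_meta.append((res.chain_id, res.seq_id, atom.name))
    moving = np.array(moving) if moving else np.zeros((0, 3))
    pairs: list = []
    if len(moving) and len(env):
        env_arr = np.array(env)
        tree = cKDTree(env_arr)
        for i, x in enumerate(moving):
            mc, ms, mn = moving_meta[i]
            mi = cont_idx.get((mc, ms))
            for j in tree.query_ball_point(x, cutoff):
                ec, es, en = env_meta[j]
                ei = cont_idx.get((ec, es))
                if mi is not None and ei is not None \
                        and abs(mi - ei) <= junction_window:
                    continue
                pairs.append(((mc, ms, mn), (ec, es, en), "x,y,z"))
    context = lattice_context or s
    if context.cell is not None and context.space_group is not None:
        full = Structure(s.residues, cell=context.cell,
                         space_group=context.space_group, id=s.id)
        meta = [(res.chain_id, res.seq_id, a.name)
                for res in s.residues for a in res.atoms if not a.is_hydrogen]
        if len(moving):
            mtree = cKDTree(moving)
            for nb in expand_neighbors(full, cutoff):
                d, idx = mtree.query(nb.coords, k=1)
                for j in np.nonzero(d <= cutoff)[0]:
                    pairs.append((moving_meta[int(idx[j])], meta[int(j)],
                                  nb.label()))
    model.clash_count = len(pairs)
    model.clash_pairs = pairs
    return len(pairs), pairs


def enumerate_rotations(host: Structure, host_anchor: tuple[str, int, int],
                        binder: Structure, binder_anchor: tuple[str, int, int],
                        k_range: Sequence[int], *,
                        lattice_context: Structure | None = None,
                        cutoff: float = 3.0, window: int = 7,
                        params: HelixParams | None = None
                        ) -> list[FusionModel]:
    """One fusion model per extension length, ranked by (clashes, k)."""
    if not len(k_range):
        raise ValueError("k_range must be non-empty")
    models = []
    for k in k_range:
        m = shared_helix_fuse(host, host_anchor, binder, binder_anchor, k,
                              window=window, params=params)
        clash_score(m, lattice_context, cutoff)
        models.append(m)
    models.sort(key=lambda m: (m.clash_count, m.k_inserted))
    return models


@dataclass(frozen=True)
class CavityEstimate:
    """Largest sphere centred at a point that avoids every lattice atom."""

    center: np.ndarray
    r_max: float   # Å; inf means unbounded (empty context)

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.r_max)


def cavity_radius(center: Sequence[float], context: Structure, *,
                  default_radius: float | None = 1.70) -> CavityEstimate:
    """Radius of the largest guest sphere at ``center`` in the packed lattice.

    ``r_max = min over heavy atoms (including symmetry mates) of
    (distance - vdW radius)``, floored at zero; a centre inside an atom gives
    zero, an empty context is unbounded.
    """
    center = np.asarray(center, dtype=float)
    xyz = context.coords(heavy_only=True)
    elements = context.elements(heavy_only=True)
    if context.cell is not None and context.space_group is not None:
        diag = math.sqrt(context.cell.a ** 2 + context.cell.b ** 2
                         + context.cell.c ** 2)
        for nb in expand_neighbors(context, cutoff=min(2 * diag, diag + 1.0),
                                   force=True):
            xyz = np.vstack([xyz, nb.coords])
            elements = list(elements) + context.elements(heavy_only=True)
    if len(xyz) == 0:
        return CavityEstimate(center=center, r_max=math.inf)
    radii = atom_radii(elements, default=default_radius)
    dist = np.linalg.norm(xyz - center, axis=1)
    return CavityEstimate(center=center,
                          r_max=float(max(0.0, (dist - radii).min())))
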