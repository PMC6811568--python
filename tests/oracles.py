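"""Independent brute-force / closed-form oracles used across the test suite.

Each oracle recomputes a quantity by a route independent of the library code
it checks: exhaustive enumeration, dense quadrature, or a direct formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_neighbors(s, cutoff: float, shift_range: int = 2
                          ) -> set[tuple[int, tuple[int, int, int]]]:
    """All (op_index, shift) whose mate has any atom within cutoff, by
    all-pairs distance over every operator and shift in [-r, r]^3."""
    from hostlattice.lattice import apply_symop, frac_cart_transform

    xyz = s.coords()
    found = set()
    shifts = range(-shift_range, shift_range + 1)
    for i, op in enumerate(s.space_group.ops):
        for shift in itertools.product(shifts, repeat=3):
            if i == 0 and shift == (0, 0, 0):
                continue
            mate = apply_symop(op, shift, (s.cell, xyz))
            if cdist(xyz, mate).min() <= cutoff:
                found.add((i, shift))
    return found


def quadrature_sasa(xyz: np.ndarray, radii: np.ndarray, probe: float,
                    n_theta: int = 180) -> float:
    """Total SASA by latitude-ring quadrature on each expanded sphere.

    Independent of the golden-spiral sampler: points come from a regular
    theta-phi grid with sin(theta) area weights.
    """
    total = 0.0
    expanded = radii + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    for i in range(len(xyz)):
        r = expanded[i]
        area_i = 0.0
        for t, w in zip(theta, np.sin(theta)):
            n_phi = max(8, int(round(2 * n_theta * math.sin(t))))
            phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
            pts = xyz[i] + r * np.stack(
                [np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi),
                 np.full(n_phi, np.cos(t))], axis=1)
            # ring weight: dA = r^2 sin(theta) dtheta dphi
            w_pt = r * r * w * (np.pi / n_theta) * (2 * np.pi / n_phi)
            if len(xyz) > 1:
                others = np.delete(np.arange(len(xyz)), i)
                d = cdist(pts, xyz[others])
                exposed = (d >= expanded[others][None, :]).all(axis=1)
            else:
                exposed = np.ones(n_phi, dtype=bool)
            area_i += exposed.sum() * w_pt
        total += area_i
    return total


def brute_force_clashes(moving: np.ndarray, environment: np.ndarray,
                        cutoff: float) -> int:
    """O(n*m) double-loop clash count."""
    return int((cdist(moving, environment) <= cutoff).sum())


def grid_search_rmsd(p: np.ndarray, q: np.ndarray, coarse_deg: float = 6.0
                     ) -> float:
    """Best superposition RMSD by exhaustive rotation grid plus local polish.

    Centroids are aligned analytically; the rotation is searched over an
    Euler-angle grid and refined with Nelder-Mead on the rotation vector.
    Never calls the implementation under test.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)

    def rmsd_of(rot_mats: np.ndarray) -> np.ndarray:
        moved = np.einsum("rij,nj->rni", rot_mats, p0)
        return np.sqrt(((moved - q0[None]) ** 2).sum(axis=(1, 2)) / len(p0))

    steps = np.arange(-180.0, 180.0, coarse_deg)
    half = np.arange(-90.0, 90.0, coarse_deg)
    grid = np.array(list(itertools.product(steps, half, steps)))
    best_rmsd, best_angles = np.inf, None
    for chunk in np.array_split(grid, max(1, len(grid) // 20000)):
        mats = Rotation.from_euler("zyz", chunk, degrees=True).as_matrix()
        vals = rmsd_of(mats)
        k = int(vals.argmin())
        if vals[k] < best_rmsd:
            best_rmsd, best_angles = float(vals[k]), chunk[k]

    def objective(rv):
        m = Rotation.from_rotvec(rv).as_matrix()
        return float(np.sqrt(((p0 @ m.T - q0) ** 2).sum() / len(p0)))

    rv0 = Rotation.from_euler("zyz", best_angles, degrees=True).as_rotvec()
    res = minimize(objective, rv0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return min(best_rmsd, float(res.fun))


def disulfide_energy_formula(d_cb: float, chi3: float, ang_a: float,
                             ang_b: float, w: tuple[float, float, float]
                             = (1.0, 1.0, 1.0)) -> float:
    """Direct transcription of the quadratic strain score."""
    dev3 = min(abs(chi3 - 87.0), abs(chi3 + 87.0))
    return (w[0] * (d_cb - 3.85) ** 2
            + w[1] * (math.radians(ang_a - 114.6) ** 2
                      + math.radians(ang_b - 114.6) ** 2)
            + w[2] * math.radians(dev3) ** 2)


def angle_close_mod360(a: float, b: float, tol: float) -> bool:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d) <= tol
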