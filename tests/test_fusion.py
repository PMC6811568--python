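"""Ideal helices, shared-helix fusion, clash scoring and cavity sizing."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from hostlattice import (
    CavityEstimate, HelixParams, UnitCell, build_ideal_helix, cavity_radius,
    clash_score, enumerate_rotations, fit_helix_axis, make_toy_crystal,
    shared_helix_fuse,
)
from hostlattice.structure_io import Atom, Residue, Structure

from oracles import angle_close_mod360, brute_force_clashes


def _cas(s):
    return np.array([r.atom("CA").xyz for r in s.residues])


class TestIdealHelix:
    def test_ca_on_cylinder_with_given_rise_and_twist(self):
        p = HelixParams()
        h = build_ideal_helix(19, p)
        ca = _cas(h)
        # 18 steps of 1.5 Å rise; 18 × 100° = 1800° = 5 full turns, so the
        # last CA sits exactly above the first (3.6 residues per turn)
        assert ca[-1, 2] - ca[0, 2] == pytest.approx(18 * p.rise)
        r = np.linalg.norm(ca[:, :2], axis=1)
        np.testing.assert_allclose(r, p.ca_radius, atol=1e-12)
        np.testing.assert_allclose(ca[0, :2], ca[-1, :2], atol=1e-9)
        # successive CAs advance by exactly the twist
        ang = np.degrees(np.unwrap(np.arctan2(ca[:, 1], ca[:, 0])))
        np.testing.assert_allclose(np.diff(ang), p.twist, atol=1e-9)

    def test_single_residue(self):
        h = build_ideal_helix(1)
        assert len(h.residues) == 1
        assert np.linalg.norm(h.residues[0].atom("CA").xyz[:2]) == \
            pytest.approx(2.3)

    def test_backbone_bond_lengths_consistent(self):
        h = build_ideal_helix(10)
        for res, nxt in zip(h.residues, h.residues[1:]):
            n_ca = np.linalg.norm(res.atom("N").xyz - res.atom("CA").xyz)
            ca_c = np.linalg.norm(res.atom("CA").xyz - res.atom("C").xyz)
            c_n = np.linalg.norm(res.atom("C").xyz - nxt.atom("N").xyz)
            assert 1.3 < n_ca < 1.6 and 1.4 < ca_c < 1.7 and 1.2 < c_n < 1.5


class TestFitHelixAxis:
    def test_round_trip_recovers_parameters(self, helix_ca18):
        fit = fit_helix_axis(helix_ca18)
        assert not fit.non_helical
        assert fit.rise == pytest.approx(1.5, abs=0.01)
        assert fit.twist == pytest.approx(100.0, abs=0.5)
        assert fit.radius == pytest.approx(2.3, abs=0.01)
        np.testing.assert_allclose(np.abs(fit.direction), [0, 0, 1],
                                   atol=1e-9)

    @pytest.mark.parametrize("rise,twist,radius", [
        (1.5, 100.0, 2.3), (1.2, 120.0, 1.9), (2.0, 80.0, 3.0),
    ])
    def test_parameter_recovery_across_geometries(self, rise, twist, radius):
        h = build_ideal_helix(12, HelixParams(rise, twist, radius))
        fit = fit_helix_axis(_cas(h))
        assert fit.rise == pytest.approx(rise, abs=0.01)
        assert fit.twist == pytest.approx(twist, abs=0.5)

    def test_rigid_motion_invariance(self, helix_ca18):
        rot = Rotation.from_euler("zxy", [33, -71, 140], degrees=True)
        moved = rot.apply(helix_ca18) + np.array([10.0, -4.0, 7.0])
        fit = fit_helix_axis(moved)
        assert fit.rise == pytest.approx(1.5, abs=0.01)
        assert fit.twist == pytest.approx(100.0, abs=0.5)

    def test_straight_line_flagged_non_helical(self):
        line = np.stack([np.arange(8) * 3.8, np.zeros(8), np.zeros(8)],
                        axis=1)
        assert fit_helix_axis(line).non_helical

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_helix_axis(np.zeros((4, 3)))

    def test_direction_points_n_to_c(self, helix_ca18):
        fit = fit_helix_axis(helix_ca18)
        assert np.dot(fit.direction, helix_ca18[-1] - helix_ca18[0]) > 0


@pytest.fixture(scope="module")
def host_binder():
    host = build_ideal_helix(20, chain_id="A", start_seq=1)
    binder = build_ideal_helix(12, chain_id="B", start_seq=1)
    return host, binder


class TestSharedHelixFuse:
    def test_k0_is_seamless_continuation(self, host_binder):
        host, binder = host_binder
        m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), k=0)
        assert m.rotation_deg == pytest.approx(0.0, abs=1e-6)
        # the fused binder anchor continues the host helix: one axis fits all
        all_ca = _cas(m.coords)
        fit = fit_helix_axis(all_ca)
        assert not fit.non_helical
        assert fit.twist == pytest.approx(100.0, abs=0.5)

    def test_rotation_equals_k_times_twist(self, host_binder):
        host, binder = host_binder
        for k in (1, 3, 4, 6, 9, 11):
            m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), k)
            assert angle_close_mod360(m.rotation_deg, k * 100.0, 1.0), \
                (k, m.rotation_deg)

    def test_full_turn_is_pure_translation(self, host_binder):
        # 18 extra residues at 100°/res = 5 turns: same orientation,
        # 27 Å further along the axis
        host, binder = host_binder
        m0 = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 0)
        m18 = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 18)
        b0 = m0.coords.select_chains(m0.binder_chain).coords()
        b18 = m18.coords.select_chains(m18.binder_chain).coords()
        delta = b18 - b0
        assert np.abs(delta - delta[0]).max() < 0.05
        assert np.linalg.norm(delta[0]) == pytest.approx(18 * 1.5, abs=0.05)
        assert angle_close_mod360(m18.rotation_deg, 0.0, 1.0)

    def test_relative_rotation_k4_vs_k9(self, host_binder):
        host, binder = host_binder
        m4 = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 4)
        m9 = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 9)
        rel = (m9.rotation_deg - m4.rotation_deg) % 360.0
        assert angle_close_mod360(rel, 140.0, 1.0)  # (9-4)*100 = 500 = 140 mod 360

    def test_binder_internal_geometry_untouched(self, host_binder):
        host, binder = host_binder
        m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 7)
        fused_binder = m.coords.select_chains(m.binder_chain)
        assert np.abs(pdist(fused_binder.coords())
                      - pdist(binder.coords())).max() < 1e-6

    def test_extension_is_alanine_with_continued_numbering(self, host_binder):
        host, binder = host_binder
        m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 3)
        assert m.extension_seqs == (21, 22, 23)
        ext = [r for r in m.coords.residues
               if r.chain_id == "A" and r.seq_id > 20]
        assert all(r.res_name == "ALA" for r in ext)

    def test_non_helical_anchor_rejected(self, host_binder):
        _, binder = host_binder
        line_res = []
        for i in range(10):
            line_res.append(Residue("A", i + 1, "GLY",
                                    [Atom(serial=i + 1, name="CA", element="C",
                                          xyz=np.array([3.8 * i, 0.0, 0.0]))]))
        straight = Structure(line_res)
        with pytest.raises(ValueError, match="helical"):
            shared_helix_fuse(straight, ("A", 1, 10), binder, ("B", 1, 12), 2)


class TestClashScore:
    def test_distant_binder_scores_zero(self, host_binder):
        host, binder = host_binder
        m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 2)
        count, pairs = clash_score(m, cutoff=3.0)
        assert count == len(pairs)
        # an ideal continuous helix has no non-bonded short contacts
        assert count == 0

    def test_matches_brute_force_double_loop(self, host_binder):
        host, binder = host_binder
        m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 2)
        # crash the binder into the host deliberately
        fused = m.coords
        host_xyz = fused.select_chains("A").coords()
        shifted = fused.coords() .copy()
        n_host = len(host_xyz)
        moving_mask = np.arange(len(shifted)) >= n_host - 5 * len(m.extension_seqs)
        m.coords = fused.with_coords(
            np.where(moving_mask[:, None],
                     shifted - np.array([0.0, 0.0, 18.0]), shifted))
        count, pairs = clash_score(m, cutoff=3.0)
        # independent O(n*m) double loop with the same continuous-helix
        # residue indexing (binder follows the extension)
        ext = set(m.extension_seqs)
        ext_end = max(ext)
        cont = {}
        pos = 0
        for res in m.coords.residues:
            if res.chain_id == "A":
                cont[("A", res.seq_id)] = res.seq_id
            elif res.chain_id == m.binder_chain:
                pos += 1
                cont[(m.binder_chain, res.seq_id)] = ext_end + pos
        moving, env = [], []
        for res in m.coords.residues:
            for a in res.atoms:
                tgt = (moving if (res.chain_id == m.binder_chain
                                  or (res.chain_id == "A" and res.seq_id in ext))
                       else env)
                tgt.append((res.chain_id, res.seq_id, a.xyz))
        brute = 0
        for mc, ms, x in moving:
            for ec, es, y in env:
                mi, ei = cont.get((mc, ms)), cont.get((ec, es))
                if mi is not None and ei is not None and abs(mi - ei) <= 4:
                    continue
                if np.linalg.norm(x - y) <= 3.0:
                    brute += 1
        assert count == brute

    def test_monotone_in_cutoff(self, host_binder):
        host, binder = host_binder
        m = shared_helix_fuse(host, ("A", 1, 20), binder, ("B", 1, 12), 5)
        counts = [clash_score(m, cutoff=c)[0] for c in (4.0, 3.0, 2.0, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestEnumerateRotations:
    def test_wall_blocks_part_of_the_rotation_circle(self, host_binder):
        host, _ = host_binder
        # binder with an off-axis "bulk" arm, as a real binder domain has:
        # anchor helix (res 1-12) plus a radial arm reaching 16 Å out
        binder_res = list(build_ideal_helix(12, chain_id="B").residues)
        serial = 500
        for i, r in enumerate(np.arange(6.0, 16.1, 2.0)):
            serial += 1
            binder_res.append(Residue("B", 13 + i, "ALA",
                                      [Atom(serial=serial, name="CA",
                                            element="C",
                                            xyz=np.array([r, 0.0, 18.0]))]))
        binder = Structure(binder_res)
        # wall: slab on the +x side only, outside the helix core, spanning
        # every height the arm can reach over the scanned k range
        wall = []
        serial = 1000
        for x in (9.0, 11.0):
            for z in np.arange(28.0, 78.0, 2.0):
                for y in np.arange(-14.0, 14.1, 2.0):
                    serial += 1
                    wall.append(Residue("W", serial, "ALA",
                                        [Atom(serial=serial, name="CA",
                                              element="C",
                                              xyz=np.array([x, y, z]))]))
        walled = Structure(list(host.residues) + wall)
        models = enumerate_rotations(walled, ("A", 1, 20), binder,
                                     ("B", 1, 12), range(0, 13), cutoff=3.0)
        assert len(models) == 13
        scores = {m.k_inserted: m.clash_count for m in models}
        assert max(scores.values()) > 0, "wall never hit — fixture broken"
        assert min(scores.values()) == 0, "no free orientation — fixture broken"
        # orientations pointing the arm at the wall rank last
        counts = [m.clash_count for m in models]
        assert counts == sorted(counts)
        # a planar wall blocks one contiguous sector of the rotation circle
        by_k = {m.k_inserted: m for m in models}
        blocked_rot = sorted(m.rotation_deg % 360.0 for m in models
                             if m.clash_count > 0)
        free_rot = [m.rotation_deg % 360.0 for m in models
                    if m.clash_count == 0]
        lo, hi = blocked_rot[0], blocked_rot[-1]
        assert hi - lo < 180.0, "blocked sector wider than the wall allows"
        assert all(not (lo < r < hi) for r in free_rot)
        # deterministic tie-break by k among equal scores
        for a, b in zip(models, models[1:]):
            if a.clash_count == b.clash_count:
                assert a.k_inserted < b.k_inserted

    def test_single_k(self, host_binder):
        host, binder = host_binder
        (m,) = enumerate_rotations(host, ("A", 1, 20), binder, ("B", 1, 12),
                                   [3])
        assert m.k_inserted == 3

    def test_empty_range_rejected(self, host_binder):
        host, binder = host_binder
        with pytest.raises(ValueError):
            enumerate_rotations(host, ("A", 1, 20), binder, ("B", 1, 12), [])

    def test_rotation_invariant_holds_for_all_models(self, host_binder):
        host, binder = host_binder
        models = enumerate_rotations(host, ("A", 1, 20), binder, ("B", 1, 12),
                                     range(0, 8))
        for m in models:
            assert angle_close_mod360(m.rotation_deg,
                                      m.k_inserted * m.twist, 1.0)


class TestCavityRadius:
    def test_single_atom_closed_form(self):
        s = Structure([Residue("A", 1, "ALA",
                               [Atom(serial=1, name="CA", element="C",
                                     xyz=np.array([10.0, 0.0, 0.0]))])])
        est = cavity_radius([0.0, 0.0, 0.0], s)
        assert est.r_max == pytest.approx(10.0 - 1.70)

    def test_empty_context_unbounded(self):
        est = cavity_radius([0, 0, 0], Structure([]))
        assert est.unbounded

    def test_center_inside_atom_gives_zero(self):
        s = Structure([Residue("A", 1, "ALA",
                               [Atom(serial=1, name="CA", element="C",
                                     xyz=np.array([0.5, 0.0, 0.0]))])])
        assert cavity_radius([0, 0, 0], s).r_max == 0.0

    def test_channel_width_matches_grid_search(self):
        # two walls of atoms at x = ±12: channel half-width 12 - r_vdw
        residues = []
        serial = 0
        for x in (-12.0, 12.0):
            for y in range(-3, 4):
                for z in range(-3, 4):
                    serial += 1
                    residues.append(Residue(
                        "A", serial, "ALA",
                        [Atom(serial=serial, name="CA", element="C",
                              xyz=np.array([x, 4.0 * y, 4.0 * z]))]))
        s = Structure(residues)
        est = cavity_radius([0.0, 0.0, 0.0], s)
        xyz = s.coords()
        grid = min(np.linalg.norm(xyz - np.zeros(3), axis=1)) - 1.70
        assert est.r_max == pytest.approx(grid, abs=0.1)
        assert est.r_max == pytest.approx(12.0 - 1.70, abs=1e-9)

    def test_monotone_under_added_atoms(self, toy_p65):
        centre = toy_p65.coords().mean(axis=0) + np.array([6.0, 0.0, 0.0])
        base = cavity_radius(centre, toy_p65).r_max
        extra = Structure(
            toy_p65.residues + [Residue("Z", 999, "ALA",
                                        [Atom(serial=9999, name="CA",
                                              element="C",
                                              xyz=centre + 3.0)])],
            cell=toy_p65.cell, space_group=toy_p65.space_group)
        assert cavity_radius(centre, extra).r_max <= base + 1e-12
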