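"""Enumerate shared-helix fusion orientations of a binder on a host helix.

Extending the shared helix by k residues advances the binder 1.5 Å per
residue along the axis and rotates it 100° per residue about it, so a k-scan
samples the rotation circle.  Here a wall of atoms blocks part of the
circle; clash counts identify the blocked orientations.
"""

import numpy as np

from hostlattice import build_ideal_helix, enumerate_rotations
from hostlattice.structure_io import Atom, Residue, Structure

host = build_ideal_helix(20, chain_id="A")

# binder: a short anchor helix plus an off-axis arm standing in for the
# bulk of a real binder domain
binder_res = list(build_ideal_helix(12, chain_id="B").residues)
for i, r in enumerate(np.arange(6.0, 16.1, 2.0)):
    binder_res.append(Residue("B", 13 + i, "ALA",
                              [Atom(serial=500 + i, name="CA", element="C",
                                    xyz=np.array([r, 0.0, 18.0]))]))
binder = Structure(binder_res)

# a wall on one side of the helix axis
wall = []
serial = 1000
for x in (9.0, 11.0):
    for z in np.arange(28.0, 78.0, 2.0):
        for y in np.arange(-14.0, 14.1, 2.0):
            serial += 1
            wall.append(Residue("W", serial, "ALA",
                                [Atom(serial=serial, name="CA", element="C",
                                      xyz=np.array([x, y, z]))]))
walled = Structure(list(host.residues) + wall)

models = enumerate_rotations(walled, ("A", 1, 20), binder, ("B", 1, 12),
                             range(0, 13), cutoff=3.0)
print(f"{'k':>3} {'rotation':>9} {'clashes':>8}")
for m in sorted(models, key=lambda m: m.k_inserted):
    print(f"{m.k_inserted:>3} {m.rotation_deg:>8.1f}° {m.clash_count:>8}")
best = models[0]
print(f"\nbest orientation: k={best.k_inserted} "
      f"({best.rotation_deg:.0f}°), {best.clash_count} clashes")
# Orientations whose rotation points the binder arm at the wall pick up
# clashes; clash-free k values are viable fusion designs.
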