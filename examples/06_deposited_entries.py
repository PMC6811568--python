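"""Checks against deposited host:guest structures (requires local files).

The quantities reported for the engineered host:guest complexes — host/guest
interface areas, domain B-factors, atom censuses, superposition RMSDs and
lattice disulfide recovery — can be recomputed from the deposited models.
This script expects the mmCIF files to be present locally (download them
from a PDB mirror into the directory given as argv[1]); it does not fetch
anything itself.

    python examples/06_deposited_entries.py /path/to/cifs

with 2ZXQ.cif, 4QEV.cif, 6QFK.cif, 6QFO.cif, 5MA6.cif in that directory.
"""

import sys
from pathlib import Path

from hostlattice import (
    crystal_contact_table, domain_bfactor, model_census, read_structure,
    scan_disulfides, superpose,
)


def main(directory: str) -> None:
    d = Path(directory)

    def have(code: str) -> Path | None:
        for suffix in (".cif", ".pdb"):
            p = d / f"{code}{suffix}"
            if p.exists():
                return p
        print(f"[skip] {code}: no file in {d}")
        return None

    if p := have("6QFK"):
        s = read_structure(p)
        c = model_census(s)
        print(f"6QFK census: {c.non_h_atoms} non-H atoms "
              f"({c.protein_atoms} protein / {c.ligand_atoms} ligand / "
              f"{c.water_atoms} water)")
        hits = scan_disulfides(s, mode="inter")
        pairs = {(a[1], b[1]) for a, b, *_ in
                 ((h.res_a, h.res_b) for h in hits)}
        print(f"6QFK inter-mate disulfide candidates: {len(hits)}; "
              f"1655/342 pair present: "
              f"{(1655, 342) in pairs or (342, 1655) in pairs}")

    if p := have("6QFO"):
        s = read_structure(p)
        stats = domain_bfactor(s, {
            "EngBF": [("A", 340, 1520)],
            "DARPin": [("A", 1541, 1694)],
        })
        for st in stats:
            print(f"6QFO mean B ({st.label}): {st.mean_b:.1f} Å² "
                  f"({st.n_atoms} atoms)")
        for h in scan_disulfides(s, mode="both")[:10]:
            print(f"  disulfide candidate {h.label()} strain={h.energy:.2f}")
        if q := have("2ZXQ"):
            res = superpose(s.select_range("A", 340, 1520),
                            read_structure(q))
            print(f"6QFO vs 2ZXQ (host domain): RMSD {res.rmsd:.2f} Å "
                  f"over {res.n_atoms} atoms")

    if p := have("4QEV"):
        s = read_structure(p)
        rows = crystal_contact_table(s, cutoff=5.0)
        for row in rows:
            print(f"4QEV contact {row.sel_a}-{row.sel_b} @ {row.op_label} "
                  f"{row.area:.1f} Å²")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
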