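# Methods

This note records the models, conventions and numerical choices behind
`hostlattice`, and what its synthetic fixtures do and do not establish about
real crystals.

## Crystal frame and symmetry

Unit cells are validated for positive lengths, angles in (0°, 180°) and a
positive-definite metric; the triclinic volume is
V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ), and the
orthogonalisation matrix follows the standard convention (a along x, b in
the xy-plane). Symmetry operators act on fractional coordinates,
x′ = R·x + t, with R integer and t held as exact rationals. Translations
are deliberately **not** wrapped modulo 1: packing tables distinguish
contacts reached by the same rotational operator in different unit cells
(e.g. the 6₅ screw appearing as both "z − 1/6" and "z + 5/6", one lattice
translation apart), and wrapping would erase that distinction. Operator
lists per Hermann–Mauguin symbol come from gemmi's compiled-in space-group
table; group closure modulo lattice translations is asserted in tests for
every group the package exercises.

Symmetry expansion enumerates all operators with lattice shifts in ±2 cells
(sufficient for any contact cutoff up to the cell edge), with an axis-wise
bounding-box rejection before the pair search; a cutoff exceeding twice the
cell diagonal is refused unless forced, because such an expansion almost
always signals a unit error in the caller. The result is ordered by
operator index then shift, so downstream tables are reproducible.

## Matthews screening

V_M = V_cell / (Z_total·MW) with Z_total = group multiplicity × molecules
per asymmetric unit; solvent fraction 1 − 1.66·v̄/V_M with the classic
protein partial specific volume v̄ = 0.74 cm³/g (so 1 − 1.2284/V_M),
clipped to [0, 1]. v̄ is configurable; 0.74 is the convention under which a
V_M of 4.38 Å³/Da corresponds to 72% solvent. Default screening thresholds
are V_M ≥ 4.3 Å³/Da and resolution ≤ 2.0 Å — the tightest bounds that admit
every entry of the bundled reference table; ranking is by V_M descending
with ties broken by resolution then accession.

## SASA and interface areas

Shrake–Rupley sampling with a golden-section spiral point set
(960 points/atom by default, probe 1.4 Å) — fully deterministic, no RNG.
The point set is oriented by the atom set's own principal axes (signs fixed
by the third moment), which makes computed areas exactly invariant under
rigid motions of the whole system; without this, finite sampling breaks
rotation invariance at the ~0.5% level. Van der Waals radii: C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80 Å, default 1.70 Å for anything else (strict
mode available). Buried interface area uses the single-interface
convention, (SASA(A) + SASA(B) − SASA(A∪B)) / 2 — stated explicitly because
both conventions circulate. Waters and non-amino-acid residues are excluded
from interface selections by default (contact tables conventionally cover
polypeptide chains); a flag includes them. Published interface areas from
unspecified software should be compared only within ~15%: probe radius,
radii set and point density all shift absolute areas.

## Ideal helices and shared-helix fusion

The ideal α-helix is parameterised by rise 1.5 Å/residue, twist
100°/residue (3.6 residues/turn) and Cα radius 2.3 Å. Backbone atoms (N,
C, O, Cβ) are placed by fixed offsets in the local cylindrical frame at
each Cα; the offsets were frozen from a dihedral-built helix
(φ = −57.8°, ψ = −47.0°), so the construct is exactly screw-symmetric and
its bond geometry is near-ideal. Axis fitting uses cross products of
successive second differences of the Cα trace (exactly axial for an ideal
helix, ≥ 5 Cαs required), an algebraic circle fit for centre and radius,
and mean axial advance / turning angle for rise and twist; traces with
radial RMS deviation above 0.25 Å, or essentially straight ones, are
flagged non-helical and refuse to anchor a fusion unless forced.

A fusion at extension k continues the host anchor helix along its own
fitted axis, phase and radius by k alanine residues, then rigid-body places
the binder by superposing the first 7 residues of its anchor helix (about
two turns — a compromise between phase accuracy and sensitivity to local
curvature; configurable) onto the next turn of the ideal continuation. The
binder's internal geometry is untouched by construction. The reported
rotation is measured, not assumed: the relative rotation of the k-placement
versus the k = 0 placement about the fitted axis; for ideal fixtures it
equals k × twist mod 360° to machine precision. Extension side chains are
modelled as alanine, since no per-k linker sequence is defined at design
time.

Clash scoring counts heavy-atom pairs below 3.0 Å between the moving part
(extension + binder) and the environment (host plus all symmetry mates of
the fused model). Residues within **4** positions of each other along the
continuous fused helix (host anchor → extension → binder) are exempt: a
continuous α-helix places O(i)···N(i+4) hydrogen-bond partners at ~2.9 Å,
which a smaller exclusion window would misreport as clashes in every
seamless fusion — the window is about helix-local structure, not only
covalent bonding. Cavity sizing is the exact minimum over lattice heavy
atoms of (distance − vdW radius), floored at zero; an empty context reports
"unbounded".

## Disulfide scan

Pre-filters: Cα–Cα ≤ 7.5 Å and Cβ–Cβ in [3.0, 5.0] Å — a generous superset
of observed disulfide geometry — with pairs closer than 2 residues in
sequence skipped. Glycine Cβ is rebuilt from N/Cα/C at ideal tetrahedral
geometry. Sγ is modelled at 1.81 Å from Cβ with the Cα–Cβ–Sγ angle at
114.6°, over the three staggered χ1 rotamers of each partner (9
combinations, best kept). The strain score is
w₁(d_Cβ−3.85)² + w₂·Σ(∠CαCβSγ−114.6°)² + w₃·dev(χ3, ±87°)², angular terms
in radians, unit weights by default: it is a unitless ranking device with
its zero at textbook disulfide geometry (d₀ = 3.85 Å Cβ–Cβ), not an energy
in physical units. Existing cysteines are scanned like any other residue
(their own Cβ is used), so engineered structures validate the scan.
Candidate recovery (presence in the list), not rank order, is the claim the
scan supports: the score deliberately ignores B-factors, sterics beyond the
bridge and sequence context.

## Rigidity analytics

Superposition is the closed-form least-squares fit: rotation from the SVD
of the covariance matrix with the smallest singular vector's sign corrected
so a reflection is never returned; collinear inputs are rejected. Atom
pairing for cross-model RMSD matches (mapped chain, author residue number,
insertion code, atom name) over heavy atoms with no outlier rejection —
reported RMSDs are plain averages, and the pair count is returned so
discrepancies from alternate conformers or unmodelled atoms are visible.
Domain B statistics are unweighted means of isotropic B over heavy atoms in
author-numbered ranges; the census partition is protein = 20 standard
residues + MSE, water = HOH/WAT, ligand = the rest, so the three classes
sum to the non-hydrogen total by construction. Author numbering is
authoritative everywhere because engineered-mutation sites are cited by
author numbers.

## Structure IO conventions

gemmi backs PDB and mmCIF parsing/writing. Alternate conformations default
to the highest-occupancy conformer (ties alphabetical by altloc); a raw
mode keeps all. Hydrogens are parsed and kept but excluded from every
geometric computation by default, matching how deposition censuses count
atoms. Fixed-column PDB output switches to hybrid-36 encoding beyond
99999 atom serials or 9999 residue numbers; mmCIF is lossless and preferred
for large fusion models. Whether deposited censuses count alternate
conformers once or per conformer is not standardised; the collapse default
counts them once.

## Synthetic fixtures: what they show

`make_toy_crystal` places a compact self-avoiding poly-alanine walk at a
general position of the asymmetric unit and rejects placements whose
symmetry copies approach below 2.0 Å; it is deterministic per seed. The toy
crystals exercise the full symmetry, contact, scan and cavity machinery at
sizes where brute-force oracles (all-operators × shifts enumeration,
O(n²) clash loops, dense quadrature SASA, grid-search superposition) run in
milliseconds. They emulate the *bookkeeping* of a real crystal — operators,
shifts, contact topology — not its chemistry: no side-chain diversity, no
waters or ligands, no coordinate error, B-factors constant. Passing tests
therefore establish the correctness of the geometry and accounting, and
say nothing about whether a particular real lattice tolerates a particular
fusion — that remains an experiment. Checks against deposited engineered
structures (interface areas, domain B means, censuses, RMSDs, recovery of
engineered bridge pairs) are provided as an example script that runs on
locally supplied files.

## Problem sizes

The test suite runs entirely on synthetic systems: toy crystals of 4–10
residues, helices of 12–20 residues, clash systems of ≤ 2000 atoms, SASA
clusters of ≤ 10 atoms for quadrature comparison, superposition sets of
3–50 points; the whole suite completes in well under a minute on one core.
The acceptance script uses the same sizes.
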