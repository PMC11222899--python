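# Methods

## Scope and model

`peptube` constructs idealised starting structures and bonded topologies
for α-D,L cyclic peptides (CPs) and their stacked nanotubes (SCPNs). The
target conformation is the flat ring: all backbone atoms near one plane,
amide C=O and N-H groups perpendicular to it, side chains equatorial. This
is the conformation that lets rings stack into β-sheet-like hydrogen-bonded
tubes, and it is only accessible when D and L stereocentres alternate —
hence the validation rule that non-glycine residues at odd (1-based)
positions are D and at even positions L, with even ring sizes from 4 to 12.
Glycine is achiral and accepted anywhere; proline is accepted with a logged
warning and never acts as a hydrogen-bond donor (no amide H). Mixed-length
stacks are rejected: rings of unequal size cannot share a registry.

The builder's output is a *tentative* geometry: internally consistent,
stereochemically correct, and regularised, but not energy-minimised under
any published force field. Production simulations are expected to run the
emitted topology, restraint and `.mdp` files through an MD engine.

## Ring construction

Backbone ring: the 3n atoms (N, Cα, C per residue, chain order) are placed
on a circle in the z = 0 plane, centred at the origin, with the first Cα on
+x. Angular spacing between consecutive atoms is proportional to the ideal
length of the connecting bond (N-Cα 1.458 Å, Cα-C 1.525 Å, C-N 1.329 Å —
standard peptide values), and the radius is

    R = l̄ / (2 sin(π / 3n)),   l̄ = mean ideal bond length,

so chord lengths approximate the ideal bond lengths to within ~0.02 Å for
all supported sizes (an octamer has R ≈ 5.51 Å). Carbonyl O sits 1.231 Å
from C along +z for odd residues and −z for even; each amide H sits 1.01 Å
from N opposite to the carbonyl of the peptide bond it shares. This seed
orientation (odd-up) is a convention; the registry scan during assembly
measures hydrogen bonding on the actual geometry, so the convention's
handedness is not load-bearing.

Cβ is placed procedurally as a true stereocentre: the two out-of-plane
tetrahedral slots at Cα are constructed from the local N/Cα/C frame with a
fixed half-tetrahedral tilt off the outward bisector, and the slot whose
scalar triple product `(N−Cα)·[(C−Cα)×(Cβ−Cα)]` has the sign demanded by
the residue's chirality receives Cβ (Hα takes the other). The sign
convention — positive is L — was frozen against independently embedded
L-configured monomers. A fixed tilt is used instead of the exact
tetrahedral solution because the flat ring's N-Cα-C angle (~165°) makes the
exact construction degenerate; the regularizer and any downstream
minimisation relax local angles afterwards.

Remaining side-chain atoms come from rigid per-residue templates
(`data/sidechain_templates.yaml`): CA-centred coordinates of an extended
L-monomer conformer, least-squares fitted (proper rotation only) onto the
as-built N/Cα/C/Cβ anchors, mirrored first for D residues. One fixed
rotamer per residue type; no rotamer search. Templates were generated once
with RDKit (ETKDG embedding + MMFF relaxation) by
`scripts/make_sidechain_templates.py` and shipped as plain text.

## Coarse-grain mapping

A mapping table assigns each residue an ordered bead list, the first always
the backbone bead BB = {N, Cα, C, O}. Beads sit at the *unweighted*
centroid of their member atoms — the common CG-builder convention; mass
weighting would shift positions by far less than a bead radius. Note a
flat-ring BB bead sits exactly 1.231/4 ≈ 0.31 Å off-plane (the carbonyl O
is the only out-of-plane member), alternating sign with residue parity.
The shipped table (`data/bead_mapping.yaml`) is MARTINI-like in
granularity (BB + ≤2 side beads) but is this package's own fixture;
published tables drop in via the same schema.

## Topologies

Coarse-grain topologies are generated directly: BB beads form a closed
cycle (n BB-BB bonds including the closure), side beads chain off in
mapping order, and the angle and proper-dihedral sets are the *complete*
enumerations of simple paths of length 2 and 3 in the bond graph — the n
cyclic BB-BB-BB and BB-BB-BB-BB backbone terms carry β-class parameters
(all residues of a flat ring are assigned the extended/β secondary
structure class), side-bead terms fall back to generic keys. Exclusions
default to one bond deep for CG.

All-atom topologies are *adapted*, never derived: a linear peptide topology
in the GROMACS dialect (pdb2gmx output, or the shipped synthetic
tetraglycine fixture with toy parameters) is cyclized by
`cyclize_linear_topology`: terminal-only particles (H2/H3 ammonium
hydrogens, OXT-like oxygens) are removed, survivors renamed to internal
names, junction charges replaced by internal-residue values, the closing
C(last)-N(1) bond added, and every angle (path of length 2 through the new
bond) and proper dihedral (path of length 3 containing it) enumerated from
the graph. Junction parameter keys are copied from an existing term with
the same atom-name pattern. Improper dihedrals spanning consecutive
residues in the template are replicated across the junction by name
pattern rather than enumerated. Exclusions are regenerated by
breadth-first search at the template's depth (default 3 bonds for AA).
`verify_cycle` audits any topology against the brute-force enumeration.

## Assembly and registry optimisation

Rings stack along +z with ring 0 fixed as built. An antiparallel interface
flips the upper ring 180° about the in-plane x axis (a proper rotation —
chirality is preserved, axial directions invert). The inter-ring spacing
(rise) defaults to 4.7 Å; experimentally the β-sheet-like stacking of
D,L-CP tubes is ~4.7–4.8 Å, and with the idealised axial amides the closest
achievable H···O contact is `rise − 2.241 Å`, so 4.7 Å yields 2.46 Å
contacts, just inside the default cutoff (4.8 Å would place them at
2.56 Å, outside it — the reason the lower end of the range is the default).

The registry angle is found by exhaustive scan: the upper ring is rotated
about the tube axis in `scan_step` increments (default 1°) over [0°, 360°),
each pose scored by counting hydrogen bonds — H···O ≤ 2.5 Å and
N-H···O ≥ 120° at the hydrogen, donors and acceptors each used at most
once via greedy best-distance matching — and the best-scoring angle wins,
smallest angle on ties. For a homo-sequence ring the score is periodic
with period 720°/n (two residues), because the amide up/down pattern
alternates with parity. Coarse-grain rings carry no hydrogens; their
registry is set geometrically (180°/n stagger for antiparallel, 0° for
parallel) and recorded with a hydrogen-bond count of zero.

## Restraints and the regularizer

Every residue's φ (C′-N-Cα-C) and ψ (N-Cα-C-N′) torsion is restrained to
its as-built value (cyclic wrap-around at the ring closure) with zero
allowed deviation and k = 1000 kJ·mol⁻¹·rad⁻² by default, exported as a
GROMACS-dialect `[dihedral_restraints]` section. The minimisation
configuration writes steepest descent with 10 000 steps, tolerance 10 and
initial step 0.01 (internal units: Å, radians, arbitrary harmonic energy).

The built-in regularizer is a geometry cleaner, not a force field: its
energy is a sum of harmonic penalties — chemical bonds at ideal lengths,
backbone angles at as-built values in the *cosine-harmonic* form
`k (cos θ − cos θ₀)²`, auxiliary backbone 1-3 and 1-4 distances at as-built
values, and the wrapped-harmonic torsion restraints. Two numerical choices
matter here and were driven by failure analysis:

- **Cosine angles.** The flat ring's backbone angles (~165°) are close to
  the θ = 180° singularity of the plain θ-harmonic gradient (∝ 1/sin θ);
  with jittered input the singular forces trapped steepest descent at a
  collinear configuration. The cosine form (GROMACS G96 angle type) keeps
  forces bounded everywhere.
- **Staged minimisation with auxiliary distance terms.** On a
  near-collinear backbone, torsions respond hypersensitively to Cartesian
  noise (the cross-product lever arms almost vanish): a 0.3 Å jitter can
  move φ/ψ readings by >150°, and the wrapped torsion penalty (cusp at
  180°) then steers descent into twisted local minima — confirmed
  independently with L-BFGS, which gets stuck at the same traps.
  `regularize_ring` therefore minimises in two stages: first the smooth
  distance-geometry network alone (bonds, angles, 1-3/1-4 distances, whose
  as-built targets encode the flat conformation without cusps — as-built
  torsions are essentially 0°/180°, where the 1-4 distance determines the
  torsion uniquely), then the full model including torsion restraints.
  Each stage's energy trace is strictly decreasing.

The steepest-descent engine itself follows the classic adaptive protocol:
a trial step displaces the largest-force particle by the current step
size; acceptance doubles the step, rejection halves it; iteration stops at
the force tolerance, the step-count budget, or step underflow. Analytic
gradients for every term are validated against central finite differences
(property test, 1e-5 relative). Torsion-gradient denominators are floored
at 1e-8 as a guard against exact collinearity; the floor is inactive in
normal operation.

## File formats and bundle

PDB output assigns one chain per ring (A–Z, a–z, 0–9: at most 62 rings,
a documented limit), residues numbered 1..n per chain, elements populated,
and a CONECT record closing each macrocycle (last backbone C to first N);
coordinates are Å at fixed-column precision (round-trip error ≤ 5·10⁻⁴ Å).
A `.gro` writer emits nanometres per that format's convention. Topology
files use the GROMACS dialect (`[moleculetype]`, `[atoms]`, `[bonds]`,
`[angles]`, `[dihedrals]` ×2 for proper/improper, `[exclusions]`), with
parameter keys preserved as trailing comments so round-trips are exact; the
emitted files are also parseable by MDAnalysis' ITP reader (verified in the
suite, with gemmi as the independent PDB reader). The index file carries
System, CP1..CPn and Backbone groups that exactly partition the system.
The final bundle is a zip archive written deterministically (fixed
timestamps, sorted members): identical requests produce byte-identical
archives. Auto-generated design names concatenate the force-field profile,
the distinct sequences, and the subunit count.

## What the fixtures do and do not show

The fixture CG mapping/parameters and the synthetic tetraglycine linear
topology exercise every pipeline mechanism — mapping coverage, parameter
lookup, cyclization, enumeration, round-trips — with realistic structure
but toy numbers. Tests passing on them demonstrate the *construction
machinery* is correct; they say nothing about the physical accuracy of any
published force field, whose parameter files users must supply. Likewise
the hydrogen-bond counts of the idealised flat stack are geometric
statements about the tentative model, not predictions of minimised
interface energetics.

## Problem sizes

The test suite and acceptance script use rings of 4–12 residues, stacks of
up to 8 rings, 20–50 random ring pairs for the registry/oracle checks
(15° scan in the randomised checks, 1° default in production builds), and
single jittered-ring regularisations — sizes chosen to exercise every
cyclic wrap-around case while keeping the whole suite in the tens of
seconds.

## Known limitations

- The tentative ring is geometrically idealised: backbone angles open
  (~165° on the circle layout), one fixed rotamer per side chain, no
  clash resolution beyond regularisation and downstream minimisation.
- No energetic (force-field) interface optimisation; the registry
  objective is purely the geometric hydrogen-bond count. Helical or tilted
  stacking modes are out of scope.
- All-atom topology generation requires a linear template per sequence
  (shipped only for tetraglycine); pdb2gmx is intentionally not
  re-implemented.
- β-, γ- and δ-amino-acid CP classes are rejected (`NOT_SUPPORTED`).
- Published force-field parameter values (Amber/CHARMM/OPLS/MARTINI and
  the chirality-sensitive MA(R/S)TINI reparameterization) are external
  data, never re-derived.
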