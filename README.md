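# peptube

Builder for **α-D,L cyclic peptides (CPs)** and their **self-assembled
cyclic peptide nanotubes (SCPNs)**: 3D structures, simulation-ready
GROMACS-dialect topologies, dihedral restraints, a built-in geometry
regularizer, and a complete output bundle — with no web service or external
MD engine in the loop.

## The problem

Cyclic peptides built from α-amino acids with strictly alternating D and L
stereocentres adopt a flat ring conformation in which every amide group
points perpendicular to the ring plane. Stacked rings then hydrogen-bond
like β-sheet strands (N-H···O=C across each interface), self-assembling
into hollow nanotubes with applications from antimicrobials to
nanoelectronics. Unlike proteins, these assemblies have no deposited
reference structures, so every simulation starts with the chore of
constructing coordinates and matching topologies by hand. `peptube`
automates that construction for researchers setting up molecular-dynamics
studies at all-atom or coarse-grain resolution, and for anyone who simply
wants a 3D model of a given CP or tube.

## What it builds

For a design of `m` subunit sequences (even length, 4–12 residues, written
in one-letter code with the first residue D) and `m − 1` parallel /
antiparallel orientation flags:

1. **Ring geometry** — the 3n backbone atoms (N, Cα, C per residue) are
   laid on a circle of radius `R = l̄ / (2 sin(π/3n))` in the z = 0 plane
   (l̄ = mean ideal bond length), carbonyl O and amide H placed axially
   with alternating parity, and side chains attached from rigid templates
   with Cβ placed as an exact stereocentre. The sign of the triple product
   `(N−Cα)·[(C−Cα)×(Cβ−Cα)]` certifies every D/L label.
2. **Topology** — coarse-grain topologies are generated from scratch
   (backbone-bead cycle plus side beads; angle and proper-dihedral sets are
   the complete simple-path enumerations of the bond graph); all-atom
   topologies are produced by cyclizing a linear pdb2gmx-style template:
   terminal particles removed, junction charges reset, the closing
   C(last)–N(1) bond added, and every bonded term spanning the junction
   enumerated from the graph.
3. **Assembly** — rings are stacked along +z at a configurable rise
   (default 4.7 Å, the β-sheet-like spacing of D,L-CP tubes). Each
   interface's **registry angle** is found by exhaustively scanning
   rotations of the upper ring and counting geometric hydrogen bonds
   (H···O ≤ 2.5 Å, N-H···O ≥ 120°, greedy best-distance matching).
4. **Restraints and regularisation** — per-residue φ/ψ restraints at their
   as-built values, an .mdp-style steepest-descent configuration (10 000
   steps by default), and a built-in two-stage steepest-descent
   regularizer over harmonic bond/angle/restraint penalties.
5. **Bundle** — a zip archive with per-CP PDBs, `nanotube.pdb` /
   `nanotube.gro`, molecule `.itp` files plus `system.top`, restraints,
   `min.mdp`, a GROMACS index file, and a JSON manifest.

Ten force-field profiles are registered (Amber03/94/96/99, OPLS-AA,
CHARMM36 at all-atom; MARTINI 2.2/2.2P/3.0 and MA(R/S)TINI at
coarse-grain). Their published parameter sets are consumed as user-supplied
data files; two `fixture-*` profiles ship with toy data so the whole
pipeline runs out of the box.

## Worked example

The classic demonstration design — eight `c-RRKWLWLW` rings stacked
antiparallel:

```python
from peptube import make_design, build_ring, stack_rings, check_chirality

design = make_design(["RRKWLWLW"] * 8, ["antiparallel"] * 7, "example")
built = [build_ring(s) for s in design.sequences]
model = stack_rings(design, built)
print("chirality of ring 1:", ",".join(check_chirality(model.rings[0])))
for i, itf in enumerate(model.interfaces):
    print(f"interface {i}: {itf.orientation}, registry {itf.registry_angle:.1f} deg, "
          f"{itf.hbond_count} H-bonds")
```

prints

```
chirality of ring 1: D,L,D,L,D,L,D,L
interface 0: antiparallel, registry 0.0 deg, 8 H-bonds
interface 1: antiparallel, registry 10.0 deg, 4 H-bonds
interface 2: antiparallel, registry 0.0 deg, 4 H-bonds
interface 3: antiparallel, registry 10.0 deg, 4 H-bonds
interface 4: antiparallel, registry 0.0 deg, 4 H-bonds
interface 5: antiparallel, registry 10.0 deg, 4 H-bonds
interface 6: antiparallel, registry 0.0 deg, 4 H-bonds
```

The first residue of every ring is D and chirality alternates around the
ring; every interface forms at least four inter-ring hydrogen bonds at its
optimal registry. The same build from the shell, with the complete output
bundle:

```sh
peptube --seq RRKWLWLW --copies 8 \
        --orient antiparallel --orient antiparallel --orient antiparallel \
        --orient antiparallel --orient antiparallel --orient antiparallel \
        --orient antiparallel \
        --ff fixture-cg --out rrkwlwlw_x8.zip
```

## Layout

- `src/peptube/sequences.py` — sequence/design validation, chirality by position
- `src/peptube/rings.py` — tentative flat-ring geometry
- `src/peptube/cgmap.py` — bead mapping (atomistic → coarse)
- `src/peptube/topology.py` — CG topology generation, AA cyclization, cycle audit
- `src/peptube/assembly.py` — flipping, H-bond scoring, registry scan, stacking
- `src/peptube/minimize.py` — restraints, harmonic model, steepest descent
- `src/peptube/formats.py` — PDB/GRO/top/itp/ndx/mdp/zip round-trippable I/O
- `src/peptube/profiles.py` — force-field profile registry
- `src/peptube/cli.py` — `peptube` command and `run_build` orchestration
- `docs/methods.md` — model, conventions, numerical choices, limitations
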