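"""Regenerate the linear tetraglycine topology fixture (fixture-aa profile).

Builds the particle/bond graph of linear GGGG with charged termini
(ammonium N-terminus with H1/H2/H3, carboxylate C-terminus with OXT),
enumerates angles and proper dihedrals exhaustively from the bond graph,
adds the standard amide-planarity impropers, and writes the result in the
GROMACS topology dialect.  This is a stand-in with toy parameters for
pdb2gmx output, synthetic by construction, shaped like the real thing.

Usage:  python scripts/make_linear_fixture.py
Writes: src/peptube/data/linear_topologies/gly4_linear.itp
"""

from __future__ import annotations

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from peptube.formats import write_molecule_itp
from peptube.topology import (
    BondedTerm,
    Particle,
    TopologySpec,
    enumerate_angles,
    enumerate_dihedrals,
    neighbor_pairs_within,
)

N_RES = 4
OUT = (
    pathlib.Path(__file__).resolve().parents[1]
    / "src" / "peptube" / "data" / "linear_topologies" / "gly4_linear.itp"
)

INTERNAL = [
    ("N", "N", -0.47), ("H", "H", 0.31), ("CA", "CT", 0.12),
    ("HA2", "H1", 0.02), ("HA3", "H1", 0.02), ("C", "C", 0.51), ("O", "O", -0.51),
]
NTERM = [
    ("N", "N3", -0.30), ("H1", "H", 0.33), ("H2", "H", 0.33), ("H3", "H", 0.33),
    ("CA", "CT", 0.25), ("HA2", "H1", 0.03), ("HA3", "H1", 0.03),
    ("C", "C", 0.51), ("O", "O", -0.51),
]
CTERM = [
    ("N", "N", -0.47), ("H", "H", 0.31), ("CA", "CT", 0.12),
    ("HA2", "H1", 0.02), ("HA3", "H1", 0.02),
    ("C", "C", 0.27), ("O", "O2", -0.635), ("OXT", "O2", -0.635),
]

BOND_PARAMS = {
    frozenset({"N", "H"}): (0.101, 363171.0),
    frozenset({"N", "CA"}): (0.1458, 282001.0),
    frozenset({"CA", "HA"}): (0.109, 284512.0),
    frozenset({"CA", "C"}): (0.1525, 259408.0),
    frozenset({"C", "O"}): (0.1231, 476976.0),
    frozenset({"C", "N"}): (0.1329, 410032.0),
}


def base_name(name: str) -> str:
    if name.startswith("HA"):
        return "HA"
    if name in ("H1", "H2", "H3"):
        return "H"
    if name == "OXT":
        return "O"
    return name


def main():
    particles = []
    index = {}
    for res in range(1, N_RES + 1):
        table = NTERM if res == 1 else CTERM if res == N_RES else INTERNAL
        for name, ptype, charge in table:
            index[(res, name)] = len(particles)
            particles.append(Particle(name, ptype, res, "GLY", charge))

    bonds = []

    def bond(a, b):
        key = f"{base_name(particles[a].name)}-{base_name(particles[b].name)}"
        b0, k = BOND_PARAMS[frozenset({base_name(particles[a].name), base_name(particles[b].name)})]
        bonds.append(BondedTerm((a, b), key, (b0, k)))

    for res in range(1, N_RES + 1):
        n, ca, c = index[(res, "N")], index[(res, "CA")], index[(res, "C")]
        for hname in ("H", "H1", "H2", "H3"):
            if (res, hname) in index:
                bond(n, index[(res, hname)])
        bond(n, ca)
        bond(ca, index[(res, "HA2")])
        bond(ca, index[(res, "HA3")])
        bond(ca, c)
        bond(c, index[(res, "O")])
        if (res, "OXT") in index:
            bond(c, index[(res, "OXT")])
        if res < N_RES:
            bond(c, index[(res + 1, "N")])

    pairs = {tuple(sorted(b.indices)) for b in bonds}
    n_part = len(particles)
    angles = [
        BondedTerm(trip, "-".join(base_name(particles[i].name) for i in trip), (110.0, 400.0))
        for trip in sorted(enumerate_angles(n_part, pairs))
    ]
    dihedrals = [
        BondedTerm(quad, "-".join(base_name(particles[i].name) for i in quad), (180.0, 1.0, 2.0))
        for quad in sorted(enumerate_dihedrals(n_part, pairs))
    ]
    # amide planarity impropers: C_i carbonyl and N_{i+1} amide centres
    for res in range(1, N_RES):
        dihedrals.append(
            BondedTerm(
                (index[(res, "CA")], index[(res + 1, "N")], index[(res, "C")], index[(res, "O")]),
                "improper-C", (180.0, 43.93), improper=True,
            )
        )
        hname = "H1" if res + 1 == 1 else "H"
        if (res + 1, hname) in index:
            dihedrals.append(
                BondedTerm(
                    (index[(res, "C")], index[(res + 1, "CA")], index[(res + 1, "N")],
                     index[(res + 1, hname)]),
                    "improper-N", (180.0, 4.6), improper=True,
                )
            )

    spec = TopologySpec(
        molecule_name="GGGG_linear",
        particles=particles,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        nrexcl=3,
    )
    spec.exclusions = sorted(neighbor_pairs_within(n_part, pairs, 3))
    spec.validate_indices()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(
        "; Linear tetraglycine topology fixture (synthetic pdb2gmx-style input\n"
        "; with toy parameters).  Regenerate: scripts/make_linear_fixture.py\n"
        + write_molecule_itp(spec)
    )
    print(f"wrote {OUT} ({len(particles)} atoms, {len(bonds)} bonds, "
          f"{len(angles)} angles, {len(dihedrals)} dihedrals)")


if __name__ == "__main__":
    main()
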