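"""Regenerate the shipped side-chain template table.

For each of the 20 standard amino acids, a single monomer is built as an
L-configured 3D conformer (RDKit ETKDG embedding + MMFF relaxation).  The
backbone anchors (N, CA, C, CB) and all side-chain atoms beyond CB are
stored CA-centred; at build time the anchors are least-squares fitted onto
the ring backbone (mirrored first for D residues) and the side-chain atoms
follow rigidly.

Usage:  python scripts/make_sidechain_templates.py
Writes: src/peptube/data/sidechain_templates.yaml
"""

from __future__ import annotations

import pathlib

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

CODES = "ACDEFGHIKLMNPQRSTVWY"
BACKBONE = {"N", "CA", "C", "O", "OXT"}
OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "peptube" / "data" / "sidechain_templates.yaml"


def hydrogen_name(heavy: str, index: int, count: int) -> str:
    suffix = heavy[1:]
    return f"H{suffix}" if count == 1 else f"H{suffix}{index}"


def build_template(code: str) -> dict:
    mol = Chem.MolFromSequence(code)
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=7) != 0:
        raise RuntimeError(f"embedding failed for {code}")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()

    named = {}
    for atom in mol.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is not None:
            named[info.GetName().strip()] = atom

    def pos(atom):
        p = conf.GetAtomPosition(atom.GetIdx())
        return [p.x, p.y, p.z]

    ca = pos(named["CA"])

    def centred(atom):
        p = pos(atom)
        return [round(p[i] - ca[i], 4) for i in range(3)]

    template = {
        "ref": {
            "N": centred(named["N"]),
            "CA": [0.0, 0.0, 0.0],
            "C": centred(named["C"]),
        },
        "atoms": [],
    }
    if code == "G":
        return template
    template["ref"]["CB"] = centred(named["CB"])

    side_heavy = [
        a
        for a in mol.GetAtoms()
        if a.GetPDBResidueInfo() is not None
        and a.GetPDBResidueInfo().GetName().strip() not in BACKBONE
        and a.GetSymbol() != "H"
    ]
    for atom in side_heavy:
        name = atom.GetPDBResidueInfo().GetName().strip()
        if name != "CB":  # CB is rebuilt procedurally for exact stereochemistry
            template["atoms"].append(
                {"name": name, "element": atom.GetSymbol(), "xyz": centred(atom)}
            )
        hydrogens = [n for n in atom.GetNeighbors() if n.GetSymbol() == "H"]
        for i, h in enumerate(hydrogens, start=1):
            template["atoms"].append(
                {
                    "name": hydrogen_name(name, i, len(hydrogens)),
                    "element": "H",
                    "xyz": centred(h),
                }
            )
    return template


def main():
    table = {code: build_template(code) for code in CODES}
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as fh:
        fh.write(
            "# Side-chain templates: CA-centred L-monomer coordinates (angstrom).\n"
            "# 'ref' anchors (N, CA, C, CB) are fitted onto the built backbone at\n"
            "# attach time (mirrored for D residues); 'atoms' follow rigidly.\n"
            "# Regenerate with scripts/make_sidechain_templates.py.\n"
        )
        yaml.safe_dump(table, fh, sort_keys=True, default_flow_style=None)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
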