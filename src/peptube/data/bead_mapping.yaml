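# Minimal coarse-grain bead mapping fixture ("fixture-cg" profile).
# One backbone bead (BB) per residue mapping N, CA, C, O, plus up to two
# side-chain beads of heavy atoms.  Bead granularity is MARTINI-like but the
# type labels and parameters are this package's own toy set; drop in a
# published mapping table (same schema) to build for a real CG force field.
# Schema: code -> list of {name, type, charge, atoms}.  BB is always first.
A:
  - {name: BB, type: P4, charge: 0.0, atoms: [N, CA, C, O]}
C:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: C5, charge: 0.0, atoms: [CB, SG]}
D:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: Qa, charge: -1.0, atoms: [CB, CG, OD1, OD2]}
E:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: Qa, charge: -1.0, atoms: [CB, CG, CD, OE1, OE2]}
F:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: SC5, charge: 0.0, atoms: [CB, CG, CD1, CD2]}
  - {name: SC2, type: SC5, charge: 0.0, atoms: [CE1, CE2, CZ]}
G:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
H:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: SC4, charge: 0.0, atoms: [CB, CG]}
  - {name: SC2, type: SP1, charge: 0.0, atoms: [ND1, CD2, CE1, NE2]}
I:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: AC1, charge: 0.0, atoms: [CB, CG1, CG2, CD1]}
K:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: C3, charge: 0.0, atoms: [CB, CG, CD]}
  - {name: SC2, type: Qd, charge: 1.0, atoms: [CE, NZ]}
L:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: AC1, charge: 0.0, atoms: [CB, CG, CD1, CD2]}
M:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: C5, charge: 0.0, atoms: [CB, CG, SD, CE]}
N:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: P5, charge: 0.0, atoms: [CB, CG, OD1, ND2]}
P:
  - {name: BB, type: P4, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: C3, charge: 0.0, atoms: [CB, CG, CD]}
Q:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: P4, charge: 0.0, atoms: [CB, CG, CD, OE1, NE2]}
R:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: N0, charge: 0.0, atoms: [CB, CG, CD]}
  - {name: SC2, type: Qd, charge: 1.0, atoms: [NE, CZ, NH1, NH2]}
S:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: P1, charge: 0.0, atoms: [CB, OG]}
T:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: P1, charge: 0.0, atoms: [CB, OG1, CG2]}
V:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: AC2, charge: 0.0, atoms: [CB, CG1, CG2]}
W:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: SC4, charge: 0.0, atoms: [CB, CG, CD1, CD2]}
  - {name: SC2, type: SNd, charge: 0.0, atoms: [NE1, CE2, CE3, CZ2, CZ3, CH2]}
Y:
  - {name: BB, type: P5, charge: 0.0, atoms: [N, CA, C, O]}
  - {name: SC1, type: SC4, charge: 0.0, atoms: [CB, CG, CD1, CD2]}
  - {name: SC2, type: SP1, charge: 0.0, atoms: [CE1, CE2, CZ, OH]}
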