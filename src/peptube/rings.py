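"""Tentative flat-ring geometry of one alpha-D,L cyclic peptide.

The ring is built in three stages:

1. :func:`build_backbone_ring` lays the 3·n backbone atoms (N, CA, C per
   residue, chain order) on a circle in the z = 0 plane.  Angular spacing
   between consecutive atoms is proportional to the ideal length of the
   connecting bond, and the radius is ``R = l̄ / (2 sin(pi / 3n))`` with
   ``l̄`` the mean ideal bond length, so chords approximate the ideal bond
   lengths closely for all supported ring sizes.
2. :func:`place_amide_atoms` adds carbonyl O and amide H perpendicular to
   the ring plane, alternating up/down with residue parity — the hallmark
   of the flat D,L conformation, which presents N-H donors on one face and
   C=O acceptors on the other at every position.
3. :func:`attach_side_chains` places CB as an exact stereocentre
   (tetrahedral construction with the chirality-controlled out-of-plane
   sign) and fits a rigid per-residue template for the remaining side-chain
   atoms, which end up pointing radially outward (equatorial).

This tentative geometry is deliberately idealised; the regularizer in
:mod:`peptube.minimize` relaxes residual strain, and production-quality
structures are expected to be minimised with a simulation engine using the
emitted topology files.

Chirality convention (frozen against an L-configured monomer): the scalar
triple product ``(N-CA) . ((C-CA) x (CB-CA))`` is positive for L and
negative for D stereocentres.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._geometry import kabsch, unit
from .errors import GeometryError
from .sequences import CPSequence

#: Ideal backbone bond lengths in angstrom (standard peptide values).
DEFAULT_BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
}
CO_LENGTH = 1.231
NH_LENGTH = 1.01
CA_CB_LENGTH = 1.53
CA_HA_LENGTH = 1.09
TETRAHEDRAL = np.deg2rad(109.47)

ATOMISTIC = "atomistic"
COARSE = "coarse"

#: Backbone particle names defining the ring cycle at each resolution.
BACKBONE_NAMES = {ATOMISTIC: ("N", "CA", "C"), COARSE: ("BB",)}

_TEMPLATE_CACHE: dict | None = None


@dataclass
class AtomRecord:
    """A labelled particle: atomistic atom or coarse-grain bead."""

    name: str
    element: str
    residue_index: int  # 1-based
    position: np.ndarray

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.residue_index, self.position.copy())


@dataclass
class RingGeometry:
    """Labelled 3D coordinates of one cyclic peptide (or its bead model)."""

    atoms: list[AtomRecord]
    sequence: CPSequence
    resolution: str = ATOMISTIC
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    cyclic: bool = True  # head-to-tail closure (restored from CONECT on read)

    @property
    def centroid(self) -> np.ndarray:
        """Mean position of the backbone particles (N/CA/C or BB beads)."""
        names = BACKBONE_NAMES[self.resolution]
        pts = np.array([a.position for a in self.atoms if a.name in names])
        return pts.mean(axis=0)

    def atom(self, residue_index: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a
        raise GeometryError("MISSING_BACKBONE", f"no atom {name} in residue {residue_index}")

    def find(self, residue_index: int, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a
        return None

    def atom_index(self, residue_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        raise GeometryError("MISSING_BACKBONE", f"no atom {name} in residue {residue_index}")

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coordinates(self, coords: np.ndarray) -> None:
        for a, row in zip(self.atoms, coords):
            a.position = np.array(row, dtype=float)

    def copy(self) -> "RingGeometry":
        return RingGeometry(
            atoms=[a.copy() for a in self.atoms],
            sequence=self.sequence,
            resolution=self.resolution,
            plane_normal=self.plane_normal.copy(),
            cyclic=self.cyclic,
        )


# canonical within-residue ordering for presentation and stable indexing
_SLOT = {"N": 0, "H": 1, "CA": 2, "HA": 3, "HA2": 3, "HA3": 4, "C": 900, "O": 901}


def _sort_ring(ring: RingGeometry) -> None:
    order_of_appearance = {id(a): i for i, a in enumerate(ring.atoms)}
    ring.atoms.sort(
        key=lambda a: (a.residue_index, _SLOT.get(a.name, 100), order_of_appearance[id(a)])
    )


def load_sidechain_templates() -> dict:
    """Load the shipped per-residue side-chain template table."""
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        ref = importlib.resources.files("peptube.data") / "sidechain_templates.yaml"
        _TEMPLATE_CACHE = yaml.safe_load(ref.read_text())
    return _TEMPLATE_CACHE


def build_backbone_ring(
    seq: CPSequence,
    bond_lengths: dict[tuple[str, str], float] | None = None,
) -> RingGeometry:
    """Lay the backbone ring atoms on a circle in the z = 0 plane.

    The first residue's CA sits on the +x axis; the chain runs
    counter-clockwise when viewed from +z (the nanotube axis).
    """
    lengths = dict(DEFAULT_BOND_LENGTHS)
    if bond_lengths:
        lengths.update(bond_lengths)
    for pair in (("N", "CA"), ("CA", "C"), ("C", "N")):
        if pair not in lengths:
            raise GeometryError("MISSING_BACKBONE", f"no ideal length for bond {pair[0]}-{pair[1]}")

    n = seq.length
    n_atoms = 3 * n
    # bond i connects ring atom i to atom i+1 (cyclic); pattern N-CA, CA-C, C-N
    bond_cycle = [lengths[("N", "CA")], lengths[("CA", "C")], lengths[("C", "N")]] * n
    total = sum(bond_cycle)
    mean_length = total / n_atoms
    radius = mean_length / (2.0 * np.sin(np.pi / n_atoms))

    theta = np.zeros(n_atoms)
    for i in range(1, n_atoms):
        theta[i] = theta[i - 1] + 2.0 * np.pi * bond_cycle[i - 1] / total
    theta -= theta[1]  # CA of residue 1 on the +x axis

    atom_names = ["N", "CA", "C"] * n
    atoms = []
    for i, name in enumerate(atom_names):
        residue = i // 3 + 1
        pos = np.array([radius * np.cos(theta[i]), radius * np.sin(theta[i]), 0.0])
        atoms.append(AtomRecord(name=name, element=name[0], residue_index=residue, position=pos))
    return RingGeometry(atoms=atoms, sequence=seq, resolution=ATOMISTIC)


def place_amide_atoms(ring: RingGeometry) -> RingGeometry:
    """Add carbonyl O and amide H perpendicular to the ring plane.

    Odd-parity residues point their C=O along +z, even along -z; each amide
    H points opposite to the carbonyl of the peptide bond its N shares
    (the bond to the preceding residue, cyclically).  Proline contributes
    no amide H.
    """
    ring = ring.copy()
    n = ring.sequence.length
    normal = ring.plane_normal

    def carbonyl_sign(residue_index: int) -> float:
        return 1.0 if residue_index % 2 == 1 else -1.0

    for res in ring.sequence.residues:
        i = res.position
        c = ring.atom(i, "C")  # raises MISSING_BACKBONE if absent
        ring.atom(i, "N")
        ring.atom(i, "CA")
        o_pos = c.position + CO_LENGTH * carbonyl_sign(i) * normal
        ring.atoms.append(AtomRecord("O", "O", i, o_pos))
        if res.code != "P":
            prev = n if i == 1 else i - 1
            h_dir = -carbonyl_sign(prev) * normal
            h_pos = ring.atom(i, "N").position + NH_LENGTH * h_dir
            ring.atoms.append(AtomRecord("H", "H", i, h_pos))
    _sort_ring(ring)
    return ring


def _tetrahedral_directions(n_pos, ca_pos, c_pos):
    """The two out-of-plane tetrahedral directions at CA, as (d_plus, d_minus)
    for the +perp and -perp branches."""
    u = unit(n_pos - ca_pos)
    v = unit(c_pos - ca_pos)
    bis = unit(u + v)
    perp = unit(np.cross(u, v))
    # Fixed half-tetrahedral tilt from the outward bisector.  The exact
    # tetrahedral solution is undefined when the backbone N-CA-C angle is
    # very open (as in the flat tentative ring, ~165 deg); a fixed mix keeps
    # CB equatorial-outward with a well-defined out-of-plane sign, and the
    # regularizer/minimisation relaxes the local angles afterwards.
    cos_gamma = np.cos(TETRAHEDRAL / 2.0)
    sin_gamma = np.sin(TETRAHEDRAL / 2.0)
    d_plus = -bis * cos_gamma + perp * sin_gamma
    d_minus = -bis * cos_gamma - perp * sin_gamma
    return d_plus, d_minus


def _triple_product_sign(n_pos, ca_pos, c_pos, cb_pos) -> float:
    return float(np.dot(n_pos - ca_pos, np.cross(c_pos - ca_pos, cb_pos - ca_pos)))


def attach_side_chains(ring: RingGeometry, templates: dict | None = None) -> RingGeometry:
    """Place CB (exact stereocentre), HA and template side-chain atoms.

    CB goes to the tetrahedral slot whose triple-product sign matches the
    residue's declared chirality; HA takes the opposite slot.  The remaining
    side-chain atoms come from the shipped rigid template, least-squares
    fitted on the N/CA/C/CB anchors (mirrored first for D residues), which
    leaves them extended and pointing away from the ring centroid.
    """
    if templates is None:
        templates = load_sidechain_templates()
    ring = ring.copy()

    for res in ring.sequence.residues:
        i = res.position
        if res.code not in templates:
            raise GeometryError("NO_TEMPLATE", f"no side-chain template for residue '{res.code}'")
        tpl = templates[res.code]
        n_pos = ring.atom(i, "N").position
        ca_pos = ring.atom(i, "CA").position
        c_pos = ring.atom(i, "C").position
        d_plus, d_minus = _tetrahedral_directions(n_pos, ca_pos, c_pos)

        if res.code == "G":
            ring.atoms.append(AtomRecord("HA2", "H", i, ca_pos + CA_HA_LENGTH * d_plus))
            ring.atoms.append(AtomRecord("HA3", "H", i, ca_pos + CA_HA_LENGTH * d_minus))
            continue

        want_positive = res.chirality == "L"
        cb_dir, ha_dir = d_plus, d_minus
        if (_triple_product_sign(n_pos, ca_pos, c_pos, ca_pos + cb_dir) > 0) != want_positive:
            cb_dir, ha_dir = d_minus, d_plus
        cb_pos = ca_pos + CA_CB_LENGTH * cb_dir
        ring.atoms.append(AtomRecord("CB", "C", i, cb_pos))
        ring.atoms.append(AtomRecord("HA", "H", i, ca_pos + CA_HA_LENGTH * ha_dir))

        ref = tpl["ref"]
        moving = np.array([ref["N"], ref["CA"], ref["C"], ref["CB"]], dtype=float)
        extra = np.array([a["xyz"] for a in tpl["atoms"]], dtype=float) if tpl["atoms"] else None
        if res.chirality == "D":
            moving = moving * np.array([-1.0, 1.0, 1.0])  # mirror the L template
            if extra is not None:
                extra = extra * np.array([-1.0, 1.0, 1.0])
        target = np.array([n_pos, ca_pos, c_pos, cb_pos])
        R, t = kabsch(moving, target)
        if extra is not None:
            placed = extra @ R.T + t
            for spec, pos in zip(tpl["atoms"], placed):
                ring.atoms.append(AtomRecord(spec["name"], spec["element"], i, pos.copy()))
    _sort_ring(ring)
    return ring


def build_ring(seq: CPSequence, templates: dict | None = None) -> RingGeometry:
    """Full tentative atomistic geometry: backbone + amides + side chains."""
    return attach_side_chains(place_amide_atoms(build_backbone_ring(seq)), templates)


def check_chirality(ring: RingGeometry) -> list[str]:
    """Classify every stereocentre from the built coordinates.

    Returns one of ``D``/``L``/``achiral`` per residue using the sign of
    the scalar triple product of (N-CA, C-CA, CB-CA); a mismatch with the
    sequence's declared pattern indicates a construction defect.
    """
    result = []
    for res in ring.sequence.residues:
        i = res.position
        if res.code == "G":
            result.append("achiral")
            continue
        sign = _triple_product_sign(
            ring.atom(i, "N").position,
            ring.atom(i, "CA").position,
            ring.atom(i, "C").position,
            ring.atom(i, "CB").position,
        )
        result.append("L" if sign > 0 else "D")
    return result


def reflect(ring: RingGeometry) -> RingGeometry:
    """Mirror image through the ring plane (negates handedness; test helper)."""
    ring = ring.copy()
    for a in ring.atoms:
        a.position = a.position * np.array([1.0, 1.0, -1.0])
    return ring
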