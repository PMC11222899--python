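"""Coarse-grain bead geometry from an atomistic ring.

A bead-mapping table assigns each residue type an ordered list of beads;
the first is always the backbone bead (BB), mapping N, CA, C and O.  Beads
are positioned at the unweighted centroid of their member atoms, the common
convention of coarse-grain structure builders (mass weighting shifts BB
positions by well under the bead radius and would add a mass table for no
testable benefit at this stage).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import yaml

from .errors import GeometryError
from .rings import ATOMISTIC, COARSE, AtomRecord, RingGeometry

_MAPPING_CACHE: dict | None = None


def load_bead_mapping() -> dict:
    """The shipped minimal bead-mapping fixture (BB + up to 2 side beads)."""
    global _MAPPING_CACHE
    if _MAPPING_CACHE is None:
        ref = importlib.resources.files("peptube.data") / "bead_mapping.yaml"
        _MAPPING_CACHE = yaml.safe_load(ref.read_text())
    return _MAPPING_CACHE


def beads_for(mapping: dict, code: str) -> list[dict]:
    try:
        return mapping[code]
    except KeyError:
        raise GeometryError("UNMAPPED_RESIDUE", f"no bead mapping for residue '{code}'") from None


def map_to_beads(ring: RingGeometry, mapping: dict | None = None) -> RingGeometry:
    """Collapse an atomistic ring to beads at member-atom centroids.

    Raises
    ------
    GeometryError
        ``UNMAPPED_RESIDUE`` if the mapping lacks a residue code present in
        the ring; ``MISSING_ATOM`` if a bead references an atom the ring
        does not contain.
    """
    if ring.resolution != ATOMISTIC:
        raise GeometryError("MISSING_ATOM", "bead mapping requires an atomistic ring")
    if mapping is None:
        mapping = load_bead_mapping()

    beads: list[AtomRecord] = []
    for res in ring.sequence.residues:
        by_name = {a.name: a for a in ring.atoms if a.residue_index == res.position}
        for bead in beads_for(mapping, res.code):
            members = []
            for atom_name in bead["atoms"]:
                if atom_name not in by_name:
                    raise GeometryError(
                        "MISSING_ATOM",
                        f"bead {bead['name']} of residue {res.code}{res.position} "
                        f"references missing atom {atom_name}",
                    )
                members.append(by_name[atom_name].position)
            centroid = np.mean(members, axis=0)
            beads.append(AtomRecord(bead["name"], "X", res.position, centroid))
    return RingGeometry(
        atoms=beads,
        sequence=ring.sequence,
        resolution=COARSE,
        plane_normal=ring.plane_normal.copy(),
    )
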