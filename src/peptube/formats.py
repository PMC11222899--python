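"""File formats: PDB/GRO structures, GROMACS-dialect topologies and index
files, and the final zip bundle.

All writers round-trip through the module's own parsers; the PDB and
topology dialects are additionally kept compatible with independent
readers (gemmi, MDAnalysis) at the documented precision.  Ring-closing
bonds are recorded as CONECT records between each chain's last backbone C
and first N so downstream viewers draw the macrocycle closed.
"""

from __future__ import annotations

import json
import string
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError
from .rings import ATOMISTIC, COARSE, AtomRecord, RingGeometry
from .assembly import NanotubeModel
from .sequences import CPSequence, NanotubeDesign, ResidueSpec, expected_chirality
from .topology import BondedTerm, Particle, TopologySpec

#: chain identifier alphabet; caps the ring count at 62
CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


def _as_model(model) -> NanotubeModel:
    if isinstance(model, RingGeometry):
        return NanotubeModel(rings=[model])
    return model


# ---------------------------------------------------------------------------
# PDB


def _pdb_atom_name(name: str) -> str:
    # names up to 3 chars start in column 14; 4-char names fill 13-16
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_pdb_str(model) -> str:
    model = _as_model(model)
    if model.n_rings > len(CHAIN_IDS):
        raise FormatError("TOO_MANY_RINGS", f"at most {len(CHAIN_IDS)} chains supported")
    lines = []
    serial = 0
    closures = []
    for ring_idx, ring in enumerate(model.rings):
        chain = CHAIN_IDS[ring_idx]
        first_n = last_c = None
        for a in ring.atoms:
            serial += 1
            res3 = THREE_LETTER[ring.sequence.residues[a.residue_index - 1].code]
            x, y, z = a.position
            element = (a.element if a.element != "X" else "")[:2]
            lines.append(
                f"ATOM  {serial:5d} {_pdb_atom_name(a.name)} {res3:<3s} {chain}{a.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            if a.name in ("N", "BB") and a.residue_index == 1 and first_n is None:
                first_n = serial
            if a.name in ("C", "BB") and a.residue_index == ring.sequence.length:
                last_c = serial
        lines.append(f"TER   {serial + 1:5d}      {res3:<3s} {chain}{ring.sequence.length:4d}")
        serial += 1
        if first_n is not None and last_c is not None:
            closures.append((last_c, first_n))
    for c, n in closures:
        lines.append(f"CONECT{c:5d}{n:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(model, path) -> Path:
    path = Path(path)
    path.write_text(write_pdb_str(model))
    return path


def read_pdb(path) -> NanotubeModel:
    """Parse a PDB produced by :func:`write_pdb` (or equivalent).

    Chains become rings; CONECT records between a chain's last backbone C
    and first N restore the ring's cyclic flag.
    """
    chains: dict[str, list[tuple[int, str, str, int]]] = {}
    positions: dict[int, np.ndarray] = {}
    order: list[str] = []
    serial_chain: dict[int, str] = {}
    conect: list[tuple[int, int]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                res3 = line[17:20].strip()
                chain = line[21]
                resi = int(line[22:26])
                pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError as exc:
                raise FormatError("PARSE_ERROR", str(exc), line=lineno) from None
            if serial in positions:
                raise FormatError("PARSE_ERROR", f"duplicate atom serial {serial}", line=lineno)
            element = line[76:78].strip() or name[0]
            if chain not in chains:
                chains[chain] = []
                order.append(chain)
            chains[chain].append((serial, name, res3, resi, element))
            positions[serial] = pos
            serial_chain[serial] = chain
        elif rec == "CONECT":
            fields = line[6:].split()
            if len(fields) >= 2:
                conect.append((int(fields[0]), int(fields[1])))

    rings = []
    closed = {ch: False for ch in order}
    for ch in order:
        records = chains[ch]
        resi_codes: dict[int, str] = {}
        for _, _, res3, resi, _ in records:
            if res3 not in ONE_LETTER:
                raise FormatError("PARSE_ERROR", f"unknown residue name {res3}")
            resi_codes[resi] = ONE_LETTER[res3]
        n = max(resi_codes)
        try:
            residues = tuple(
                ResidueSpec(resi_codes[i], i, expected_chirality(resi_codes[i], i))
                for i in range(1, n + 1)
            )
        except KeyError as exc:
            raise FormatError("PARSE_ERROR", f"missing residue {exc} in chain {ch}") from None
        seq = CPSequence(residues=residues)
        atoms = [
            AtomRecord(name, element, resi, positions[serial])
            for serial, name, _, resi, element in records
        ]
        resolution = COARSE if any(a.name == "BB" for a in atoms) else ATOMISTIC
        rings.append(RingGeometry(atoms=atoms, sequence=seq, resolution=resolution))
    for a, b in conect:
        if serial_chain.get(a) == serial_chain.get(b) and serial_chain.get(a) is not None:
            closed[serial_chain[a]] = True
    for ch, ring in zip(order, rings):
        ring.cyclic = closed[ch]
    return NanotubeModel(rings=rings)


def write_gro_str(model, title: str = "peptube model") -> str:
    """GRO coordinates (nanometres, per the format's convention)."""
    model = _as_model(model)
    atoms = []
    for ring_idx, ring in enumerate(model.rings):
        for a in ring.atoms:
            res3 = THREE_LETTER[ring.sequence.residues[a.residue_index - 1].code]
            atoms.append((ring_idx, a, res3))
    lines = [title, f"{len(atoms):5d}"]
    serial = 0
    for ring_idx, a, res3 in atoms:
        serial += 1
        resnum = ring_idx * 100 + a.residue_index  # unique-ish per ring
        x, y, z = a.position / 10.0
        lines.append(f"{resnum:5d}{res3:<5s}{a.name:>5s}{serial:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{10.0:10.5f}{10.0:10.5f}{10.0:10.5f}")
    return "\n".join(lines) + "\n"


def write_gro(model, path) -> Path:
    path = Path(path)
    path.write_text(write_gro_str(model))
    return path


# ---------------------------------------------------------------------------
# GROMACS topology dialect


def _term_line(term: BondedTerm, func: int) -> str:
    idx = "".join(f"{i + 1:6d}" for i in term.indices)
    params = "".join(f" {p:12.6g}" for p in term.params)
    comment = f"  ; {term.key}" if term.key else ""
    return f"{idx}{func:6d}{params}{comment}"


def write_molecule_itp(spec: TopologySpec) -> str:
    lines = ["[ moleculetype ]", "; name  nrexcl", f"{spec.molecule_name}  {spec.nrexcl}", ""]
    lines += ["[ atoms ]", ";  nr  type  resnr  residue  atom  cgnr  charge"]
    for i, p in enumerate(spec.particles, start=1):
        lines.append(
            f"{i:6d}  {p.type:<6s}{p.residue_index:5d}  {p.residue_name:<5s}{p.name:<6s}{i:5d}{p.charge:9.3f}"
        )
    if spec.bonds:
        lines += ["", "[ bonds ]"]
        lines += [_term_line(b, 1) for b in spec.bonds]
    if spec.angles:
        lines += ["", "[ angles ]"]
        lines += [_term_line(a, 1) for a in spec.angles]
    propers = [d for d in spec.dihedrals if not d.improper]
    impropers = [d for d in spec.dihedrals if d.improper]
    if propers:
        lines += ["", "[ dihedrals ]"]
        lines += [_term_line(d, 1) for d in propers]
    if impropers:
        lines += ["", "[ dihedrals ]"]
        lines += [_term_line(d, 2) for d in impropers]
    if spec.exclusions:
        lines += ["", "[ exclusions ]"]
        for i, j in spec.exclusions:
            lines.append(f"{i + 1:6d}{j + 1:6d}")
    return "\n".join(lines) + "\n"


def parse_molecule_itp(text: str) -> TopologySpec:
    section = None
    molecule_name = "UNNAMED"
    nrexcl = 3
    particles: list[Particle] = []
    bonds: list[BondedTerm] = []
    angles: list[BondedTerm] = []
    dihedrals: list[BondedTerm] = []
    exclusions: list[tuple[int, int]] = []
    n_indices = {"bonds": 2, "angles": 3, "dihedrals": 4}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        code, _, comment = raw.partition(";")
        key_comment = comment.strip()
        line = code.strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            continue
        try:
            if section == "moleculetype":
                parts = line.split()
                molecule_name, nrexcl = parts[0], int(parts[1])
            elif section == "atoms":
                parts = line.split()
                particles.append(
                    Particle(
                        name=parts[4],
                        type=parts[1],
                        residue_index=int(parts[2]),
                        residue_name=parts[3],
                        charge=float(parts[6]) if len(parts) > 6 else 0.0,
                    )
                )
            elif section in n_indices:
                k = n_indices[section]
                parts = line.split()
                indices = tuple(int(p) - 1 for p in parts[:k])
                func = int(parts[k])
                params = tuple(float(p) for p in parts[k + 1 :])
                term = BondedTerm(
                    indices, key_comment, params, improper=(section == "dihedrals" and func == 2)
                )
                {"bonds": bonds, "angles": angles, "dihedrals": dihedrals}[section].append(term)
            elif section == "exclusions":
                parts = [int(p) - 1 for p in line.split()]
                for j in parts[1:]:
                    pair = tuple(sorted((parts[0], j)))
                    if pair not in exclusions:
                        exclusions.append(pair)
        except (ValueError, IndexError) as exc:
            raise FormatError("PARSE_ERROR", str(exc), line=lineno) from None
    return TopologySpec(
        molecule_name=molecule_name,
        particles=particles,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        exclusions=sorted(exclusions),
        nrexcl=nrexcl,
    )


def write_topology(
    specs: list[TopologySpec],
    system_name: str,
    molecule_order: list[str] | None = None,
) -> dict[str, str]:
    """Emit one .itp per distinct molecule plus the system-level .top.

    ``molecule_order`` lists molecule names in stack order (defaults to one
    instance of each spec); consecutive runs collapse into counts, as the
    [molecules] section requires.
    """
    by_name: dict[str, TopologySpec] = {}
    for spec in specs:
        if spec.molecule_name in by_name and by_name[spec.molecule_name] is not spec:
            raise FormatError(
                "DUPLICATE_MOLECULE_NAME", f"two molecules named {spec.molecule_name}"
            )
        by_name[spec.molecule_name] = spec
    files = {f"{name}.itp": write_molecule_itp(spec) for name, spec in by_name.items()}

    if molecule_order is None:
        molecule_order = [s.molecule_name for s in specs]
    runs: list[tuple[str, int]] = []
    for name in molecule_order:
        if name not in by_name:
            raise FormatError("DUPLICATE_MOLECULE_NAME", f"unknown molecule {name} in order")
        if runs and runs[-1][0] == name:
            runs[-1] = (name, runs[-1][1] + 1)
        else:
            runs.append((name, 1))
    top_lines = [f"; system topology for {system_name}"]
    top_lines += [f'#include "{name}.itp"' for name in by_name]
    top_lines += ["", "[ system ]", system_name, "", "[ molecules ]", "; name  count"]
    top_lines += [f"{name}  {count}" for name, count in runs]
    files["system.top"] = "\n".join(top_lines) + "\n"
    return files


def parse_system_top(text: str) -> tuple[str, list[tuple[str, int]]]:
    """System name and [molecules] counts from a .top written here."""
    section = None
    system_name = ""
    molecules: list[tuple[str, int]] = []
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            continue
        if section == "system":
            system_name = line
        elif section == "molecules":
            name, count = line.split()
            molecules.append((name, int(count)))
    return system_name, molecules


# ---------------------------------------------------------------------------
# index files


def make_index_groups(model) -> dict[str, list[int]]:
    """System, one group per ring (CP1..CPn) and Backbone, 1-based."""
    model = _as_model(model)
    groups: dict[str, list[int]] = {"System": []}
    backbone: list[int] = []
    serial = 0
    for ring_idx, ring in enumerate(model.rings, start=1):
        group = []
        names = ("BB",) if ring.resolution == COARSE else ("N", "CA", "C")
        for a in ring.atoms:
            serial += 1
            group.append(serial)
            groups["System"].append(serial)
            if a.name in names:
                backbone.append(serial)
        groups[f"CP{ring_idx}"] = group
    groups["Backbone"] = backbone
    return groups


def write_index_str(model) -> str:
    lines = []
    for name, indices in make_index_groups(model).items():
        lines.append(f"[ {name} ]")
        for start in range(0, len(indices), 15):
            lines.append(" ".join(f"{i:5d}" for i in indices[start : start + 15]))
    return "\n".join(lines) + "\n"


def write_index(model, path) -> Path:
    path = Path(path)
    path.write_text(write_index_str(model))
    return path


def parse_index(text: str) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            current = line.strip("[] \t")
            groups[current] = []
        elif current is not None:
            groups[current].extend(int(p) for p in line.split())
    return groups


# ---------------------------------------------------------------------------
# bundle


@dataclass
class BuildBundle:
    """The complete output artifact set, as member-name -> text."""

    members: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, text: str) -> None:
        self.members[name] = text


def auto_name(profile_name: str, design: NanotubeDesign) -> str:
    """Design name encoding the force-field profile and the sequences."""
    seqs = []
    for s in design.sequences:
        if s.text not in seqs:
            seqs.append(s.text)
    token = "-".join(seqs)
    return f"{profile_name}_{token}_x{design.n_subunits}"


def write_bundle(bundle: BuildBundle, path) -> Path:
    """Write all members into one zip archive, deterministically (fixed
    timestamps, sorted member order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(bundle.members):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, bundle.members[name])
    return path


def make_manifest(design: NanotubeDesign, profile_name: str, extra: dict | None = None) -> str:
    from . import __version__

    payload = {
        "name": design.name,
        "forcefield": profile_name,
        "sequences": [s.text for s in design.sequences],
        "orientations": list(design.orientations),
        "version": __version__,
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
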