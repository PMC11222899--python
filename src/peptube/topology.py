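"""Bonded topologies for cyclic molecules.

Two routes produce a head-to-tail cyclic topology:

* :func:`generate_cg_topology` builds a coarse-grain topology from scratch:
  the backbone beads form a closed cycle (n bonds, n consecutive angle
  triples, n consecutive dihedral quadruples, all cyclic), side-chain beads
  hang off in mapping order, and every residue is assigned the
  extended/beta secondary-structure class, matching the flat,
  beta-sheet-like ring conformation.

* :func:`cyclize_linear_topology` adapts a linear peptide topology (the
  kind emitted by pdb2gmx, shipped here as fixture templates or supplied by
  the user): terminal-only particles are removed, junction charges reset to
  internal-residue values, the closing C(last)-N(1) bond added, and every
  angle/proper-dihedral spanning the junction enumerated from the bond
  graph.  pdb2gmx itself is never re-implemented.

Angle and proper-dihedral completeness is defined graph-theoretically:
angles are simple paths of length 2 and proper dihedrals simple paths of
length 3 in the bond graph.  :func:`verify_cycle` re-derives both sets by
brute force and checks the backbone is a single cycle.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

from .errors import TopologyError
from .sequences import CPSequence

#: Particle names that exist only at chain termini in supported linear
#: templates: N-terminal ammonium hydrogens and C-terminal oxygens.
TERMINAL_ONLY_NAMES = ("H2", "H3", "HT2", "HT3", "OXT", "OC2", "OT2")
#: Renames applied at the junction so surviving particles carry internal names.
TERMINAL_RENAMES = {"H1": "H", "HT1": "H", "OC1": "O", "OT1": "O"}

BACKBONE_AA = ("N", "CA", "C")
BACKBONE_CG = ("BB",)

SS_EXTENDED = "E"


@dataclass(frozen=True)
class Particle:
    name: str
    type: str
    residue_index: int
    residue_name: str
    charge: float


@dataclass(frozen=True)
class BondedTerm:
    """A bond, angle or dihedral: particle indices (0-based), a parameter
    key, numeric parameters for file output, and an improper flag."""

    indices: tuple[int, ...]
    key: str = ""
    params: tuple[float, ...] = ()
    improper: bool = False


@dataclass
class TopologySpec:
    """Bonded description of one molecule (GROMACS-style)."""

    molecule_name: str
    particles: list[Particle]
    bonds: list[BondedTerm] = field(default_factory=list)
    angles: list[BondedTerm] = field(default_factory=list)
    dihedrals: list[BondedTerm] = field(default_factory=list)
    exclusions: list[tuple[int, int]] = field(default_factory=list)
    nrexcl: int = 3

    @property
    def total_charge(self) -> float:
        return sum(p.charge for p in self.particles)

    def bond_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted(b.indices)) for b in self.bonds}

    def validate_indices(self) -> None:
        n = len(self.particles)
        for group in (self.bonds, self.angles, self.dihedrals):
            for term in group:
                if any(i < 0 or i >= n for i in term.indices):
                    raise TopologyError("BAD_TERM", f"index out of range in {term.indices}")
        seen = set()
        for b in self.bonds:
            pair = tuple(sorted(b.indices))
            if pair in seen:
                raise TopologyError("BAD_TERM", f"duplicate bond {pair}")
            seen.add(pair)

    def backbone_indices(self) -> list[int]:
        names = BACKBONE_CG if any(p.name == "BB" for p in self.particles) else BACKBONE_AA
        return [i for i, p in enumerate(self.particles) if p.name in names]


# ---------------------------------------------------------------------------
# graph enumeration


def adjacency(n: int, pairs: set[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _canonical(path: tuple[int, ...]) -> tuple[int, ...]:
    return min(path, path[::-1])


def enumerate_angles(n: int, pairs: set[tuple[int, int]]) -> set[tuple[int, int, int]]:
    """All simple paths of length 2 (i-j-k) in the bond graph."""
    adj = adjacency(n, pairs)
    found = set()
    for j in range(n):
        neigh = sorted(adj[j])
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                found.add(_canonical((neigh[a], j, neigh[b])))
    return found


def enumerate_dihedrals(n: int, pairs: set[tuple[int, int]]) -> set[tuple[int, int, int, int]]:
    """All simple paths of length 3 (i-j-k-l) in the bond graph."""
    adj = adjacency(n, pairs)
    found = set()
    for j, k in pairs:
        for jj, kk in ((j, k), (k, j)):
            for i in adj[jj] - {kk}:
                for l in adj[kk] - {jj, i}:
                    found.add(_canonical((i, jj, kk, l)))
    return found


def neighbor_pairs_within(n: int, pairs: set[tuple[int, int]], depth: int) -> set[tuple[int, int]]:
    """All particle pairs at bond-graph distance 1..depth (exclusion set)."""
    adj = adjacency(n, pairs)
    out = set()
    for start in range(n):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            if dist[node] == depth:
                continue
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    queue.append(nb)
        for node, d in dist.items():
            if 0 < d and node > start:
                out.add((start, node))
    return out


def is_single_cycle(nodes: list[int], pairs: set[tuple[int, int]]) -> bool:
    """True when the induced subgraph on ``nodes`` is one simple cycle."""
    node_set = set(nodes)
    sub = {(i, j) for i, j in pairs if i in node_set and j in node_set}
    if len(sub) != len(nodes) or len(nodes) < 3:
        return False
    adj: dict[int, set[int]] = {v: set() for v in nodes}
    for i, j in sub:
        adj[i].add(j)
        adj[j].add(i)
    if any(len(v) != 2 for v in adj.values()):
        return False
    # connectivity
    seen = {nodes[0]}
    queue = deque([nodes[0]])
    while queue:
        for nb in adj[queue.popleft()]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return len(seen) == len(nodes)


# ---------------------------------------------------------------------------
# CG generation


def _param_lookup(table: dict, section: str, candidates: list[str]) -> tuple[str, tuple[float, ...]]:
    entries = table.get(section, {})
    for key in candidates:
        if key in entries:
            vals = entries[key]
            return key, tuple(float(v) for v in vals.values())
    raise TopologyError(
        "MISSING_PARAM", f"no {section[:-1]} parameters under any of {candidates}"
    )


def _role(bead_name: str) -> str:
    return "SC" if bead_name.startswith("SC") else bead_name


def generate_cg_topology(
    seq: CPSequence,
    mapping: dict,
    params: dict,
    molecule_name: str = "CP",
    nrexcl: int = 1,
) -> TopologySpec:
    """Coarse-grain cyclic topology for one ring.

    The BB beads form a closed cycle; every consecutive BB triple becomes an
    angle and every consecutive quadruple a dihedral (n of each, cyclically).
    Side beads chain off their BB in mapping order (BB-SC1, SC1-SC2, ...).
    All residues use the extended/beta secondary-structure class for
    parameter lookup.
    """
    from .cgmap import beads_for  # local import to avoid cycle

    particles: list[Particle] = []
    bb_index: list[int] = []
    side_indices: list[list[int]] = []
    for res in seq.residues:
        chain: list[int] = []
        for k, bead in enumerate(beads_for(mapping, res.code)):
            idx = len(particles)
            particles.append(
                Particle(bead["name"], bead["type"], res.position, res.code, float(bead["charge"]))
            )
            if k == 0:
                bb_index.append(idx)
            else:
                chain.append(idx)
        side_indices.append(chain)

    n = seq.length
    ss = SS_EXTENDED
    bonds: list[BondedTerm] = []
    key, vals = _param_lookup(params, "bonds", [f"BB-BB:{ss}", "BB-BB"])
    for i in range(n):
        bonds.append(BondedTerm((bb_index[i], bb_index[(i + 1) % n]), key, vals))
    for res, chain in zip(seq.residues, side_indices):
        prev = bb_index[res.position - 1]
        prev_name = "BB"
        for idx in chain:
            name = particles[idx].name
            key, vals = _param_lookup(
                params,
                "bonds",
                [f"{res.code}:{prev_name}-{name}", f"{_role(prev_name)}-{_role(name)}:{ss}",
                 f"{_role(prev_name)}-{_role(name)}"],
            )
            bonds.append(BondedTerm((prev, idx), key, vals))
            prev, prev_name = idx, name

    # Angles and proper dihedrals are the complete brute-force sets from the
    # bond graph (paths of length 2 and 3): the n cyclic BB-BB-BB and
    # BB-BB-BB-BB backbone terms carry beta-class parameters, terms touching
    # side beads fall back to generic keys.
    pairs = {tuple(sorted(b.indices)) for b in bonds}

    def roles_of(indices: tuple[int, ...]) -> list[str]:
        return [_role(particles[i].name) for i in indices]

    angles = []
    for trip in sorted(enumerate_angles(len(particles), pairs)):
        r = roles_of(trip)
        key, vals = _param_lookup(
            params, "angles",
            [f"{'-'.join(r)}:{ss}", "-".join(r), f"{'-'.join(r[::-1])}:{ss}",
             "-".join(r[::-1]), "default"],
        )
        angles.append(BondedTerm(trip, key, vals))
    dihedrals = []
    for quad in sorted(enumerate_dihedrals(len(particles), pairs)):
        r = roles_of(quad)
        key, vals = _param_lookup(
            params, "dihedrals",
            [f"{'-'.join(r)}:{ss}", "-".join(r), f"{'-'.join(r[::-1])}:{ss}",
             "-".join(r[::-1]), "default"],
        )
        dihedrals.append(BondedTerm(quad, key, vals))

    top = TopologySpec(
        molecule_name=molecule_name,
        particles=particles,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        nrexcl=nrexcl,
    )
    top.exclusions = sorted(neighbor_pairs_within(len(particles), top.bond_pairs(), nrexcl))
    top.validate_indices()
    return top


# ---------------------------------------------------------------------------
# AA cyclization


def _find_linear_backbone(top: TopologySpec) -> list[int]:
    named = [i for i, p in enumerate(top.particles) if p.name in BACKBONE_AA]
    if len(named) >= 3:
        return named
    return list(range(len(top.particles)))


def _junction_endpoints(top: TopologySpec, backbone: list[int]) -> tuple[int, int]:
    """(first, last) particles of the linear backbone, by graph degree."""
    bset = set(backbone)
    pairs = {p for p in top.bond_pairs() if p[0] in bset and p[1] in bset}
    if is_single_cycle(backbone, top.bond_pairs()):
        raise TopologyError("NOT_LINEAR", "backbone is already cyclic")
    deg: dict[int, int] = {v: 0 for v in backbone}
    for i, j in pairs:
        deg[i] += 1
        deg[j] += 1
    ends = sorted(v for v, d in deg.items() if d == 1)
    if len(ends) != 2:
        raise TopologyError(
            "JUNCTION_AMBIGUOUS", f"expected 2 backbone chain ends, found {len(ends)}"
        )
    first, last = ends[0], ends[1]
    # orient: the head is residue 1's N when names are available
    if top.particles[first].residue_index > top.particles[last].residue_index:
        first, last = last, first
    return first, last


def _match_key(terms: list[BondedTerm], particles: list[Particle], names: tuple[str, ...]):
    """Parameter key/params of an existing term with the same name pattern."""
    for t in terms:
        tn = tuple(particles[i].name for i in t.indices)
        if tn == names or tn == names[::-1]:
            return t.key, t.params
    if terms:
        return terms[0].key, terms[0].params
    return "", ()


def cyclize_linear_topology(
    linear: TopologySpec,
    internal_charges: dict[str, float] | None = None,
) -> TopologySpec:
    """Close a linear peptide topology head-to-tail.

    Terminal-only particles (``H2``/``H3`` ammonium hydrogens, ``OXT``-like
    carboxylate oxygens — see :data:`TERMINAL_ONLY_NAMES`) are removed and
    survivors renamed to internal names; junction-particle charges are
    replaced from ``internal_charges`` (name -> charge, applied on the first
    and last residues only); the closing bond is added and all bonded terms
    spanning it are enumerated from the bond graph (angles: paths of length
    2 through the new bond; proper dihedrals: paths of length 3 containing
    it).  Improper dihedrals spanning consecutive residues in the template
    are replicated across the junction by name pattern.  Exclusions are
    regenerated at the input's ``nrexcl`` depth.
    """
    linear.validate_indices()
    backbone = _find_linear_backbone(linear)
    first, last = _junction_endpoints(linear, backbone)

    first_res = linear.particles[first].residue_index
    last_res = linear.particles[last].residue_index

    # --- remove terminal-only particles, rename and recharge the rest
    remove = {
        i
        for i, p in enumerate(linear.particles)
        if p.residue_index in (first_res, last_res) and p.name in TERMINAL_ONLY_NAMES
    }
    old_to_new: dict[int, int] = {}
    particles: list[Particle] = []
    for i, p in enumerate(linear.particles):
        if i in remove:
            continue
        name = p.name
        if p.residue_index in (first_res, last_res) and name in TERMINAL_RENAMES:
            name = TERMINAL_RENAMES[name]
        charge = p.charge
        if internal_charges and p.residue_index in (first_res, last_res):
            if name in internal_charges:
                charge = internal_charges[name]
        old_to_new[i] = len(particles)
        particles.append(replace(p, name=name, charge=charge))

    def remap_terms(terms: list[BondedTerm]) -> list[BondedTerm]:
        out = []
        for t in terms:
            if any(i in remove for i in t.indices):
                continue
            out.append(replace(t, indices=tuple(old_to_new[i] for i in t.indices)))
        return out

    bonds = remap_terms(linear.bonds)
    angles = remap_terms(linear.angles)
    propers = remap_terms([d for d in linear.dihedrals if not d.improper])
    impropers = remap_terms([d for d in linear.dihedrals if d.improper])

    nfirst, nlast = old_to_new[first], old_to_new[last]
    npart = len(particles)

    # --- closing bond, typed like an existing C-N (or first) bond
    key, vals = _match_key(
        bonds, particles, (particles[nlast].name, particles[nfirst].name)
    )
    bonds.append(BondedTerm((nlast, nfirst), key, vals))
    pairs = {tuple(sorted(b.indices)) for b in bonds}

    # --- junction angles and proper dihedrals by graph enumeration
    new_bond = tuple(sorted((nlast, nfirst)))
    have_angles = {_canonical(a.indices) for a in angles}
    for trip in sorted(enumerate_angles(npart, pairs)):
        if new_bond in {tuple(sorted(trip[:2])), tuple(sorted(trip[1:]))} and trip not in have_angles:
            names = tuple(particles[i].name for i in trip)
            k, v = _match_key(angles, particles, names)
            angles.append(BondedTerm(trip, k, v))
    have_dihedrals = {_canonical(d.indices) for d in propers}
    for quad in sorted(enumerate_dihedrals(npart, pairs)):
        inner = [tuple(sorted(quad[i : i + 2])) for i in range(3)]
        if new_bond in inner and quad not in have_dihedrals:
            names = tuple(particles[i].name for i in quad)
            k, v = _match_key(propers, particles, names)
            propers.append(BondedTerm(quad, k, v))

    # --- junction impropers copied from the internal-residue pattern
    by_res_name: dict[tuple[int, str], int] = {
        (p.residue_index, p.name): i for i, p in enumerate(particles)
    }
    n_res = max(p.residue_index for p in particles)
    have_impropers = {_canonical(d.indices) for d in impropers}
    junction_impropers: list[BondedTerm] = []
    for t in impropers:
        res = [particles[i].residue_index for i in t.indices]
        lo = min(res)
        if max(res) - lo != 1:
            continue
        # instantiate the same pattern across last_res -> first_res
        pattern = [(particles[i].name, particles[i].residue_index - lo) for i in t.indices]
        mapped = []
        for name, offset in pattern:
            res_idx = last_res if offset == 0 else first_res
            idx = by_res_name.get((res_idx, name))
            if idx is None:
                mapped = None
                break
            mapped.append(idx)
        if mapped and _canonical(tuple(mapped)) not in have_impropers:
            term = BondedTerm(tuple(mapped), t.key, t.params, improper=True)
            junction_impropers.append(term)
            have_impropers.add(_canonical(tuple(mapped)))
    impropers.extend(junction_impropers)

    cyclic = TopologySpec(
        molecule_name=linear.molecule_name,
        particles=particles,
        bonds=bonds,
        angles=angles,
        dihedrals=propers + impropers,
        nrexcl=linear.nrexcl,
    )
    cyclic.exclusions = sorted(neighbor_pairs_within(npart, pairs, linear.nrexcl))
    cyclic.validate_indices()
    return cyclic


# ---------------------------------------------------------------------------
# verification


@dataclass
class CycleReport:
    """Structural audit of a cyclic topology against brute-force enumeration."""

    backbone_is_cycle: bool
    backbone_size: int
    expected_size: int | None
    angles_missing: int
    angles_extra: int
    dihedrals_missing: int
    dihedrals_extra: int

    @property
    def ok(self) -> bool:
        size_ok = self.expected_size is None or self.backbone_size == self.expected_size
        return (
            self.backbone_is_cycle
            and size_ok
            and self.angles_missing == 0
            and self.dihedrals_missing == 0
        )


def verify_cycle(top: TopologySpec, expected_size: int | None = None) -> CycleReport:
    """Check the backbone bonded graph is one simple cycle and the
    angle/proper-dihedral sets match brute-force path enumeration."""
    backbone = top.backbone_indices()
    pairs = top.bond_pairs()
    n = len(top.particles)
    want_angles = enumerate_angles(n, pairs)
    want_dihedrals = enumerate_dihedrals(n, pairs)
    got_angles = {_canonical(a.indices) for a in top.angles}
    got_dihedrals = {_canonical(d.indices) for d in top.dihedrals if not d.improper}
    return CycleReport(
        backbone_is_cycle=is_single_cycle(backbone, pairs),
        backbone_size=len(backbone),
        expected_size=expected_size,
        angles_missing=len(want_angles - got_angles),
        angles_extra=len(got_angles - want_angles),
        dihedrals_missing=len(want_dihedrals - got_dihedrals),
        dihedrals_extra=len(got_dihedrals - want_dihedrals),
    )
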