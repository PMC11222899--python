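"""Backbone dihedral restraints and a built-in steepest-descent regularizer.

The restraints pin every residue's phi (C_prev-N-CA-C) and psi
(N-CA-C-N_next) torsion to its as-built value, keeping the ring "open"
(flat, amides axial) while bond and angle terms relax local strain.  The
minimizer itself is a geometry regularizer over harmonic bond, angle and
dihedral-restraint penalties — deliberately *not* a force-field: structures
meant for production simulation should be re-minimised by an MD engine
using the emitted topology and run-parameter files.

Units are internal: angstrom for lengths, radians for angles, energies in
arbitrary harmonic units (only relative stiffness matters for
regularisation).  The steepest-descent protocol is the classic adaptive
one: a trial step moves the largest-force particle by the current step
size; acceptance (energy decreased) doubles the step, rejection halves it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import angle_between, dihedral
from .errors import GeometryError, TopologyError
from .rings import (
    ATOMISTIC,
    CA_CB_LENGTH,
    CO_LENGTH,
    DEFAULT_BOND_LENGTHS,
    NH_LENGTH,
    RingGeometry,
)

DEFAULT_RESTRAINT_K = 1000.0  # kJ mol^-1 rad^-2 when exported; internal units here
DEFAULT_BOND_K = 1000.0
DEFAULT_ANGLE_K = 100.0


@dataclass(frozen=True)
class DihedralRestraint:
    indices: tuple[int, int, int, int]
    target_deg: float
    deviation_deg: float
    k: float


@dataclass
class RestraintSet:
    """Per-residue phi/psi restraints of one atomistic ring."""

    entries: list[DihedralRestraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MinimizationConfig:
    integrator: str = "steep"
    nsteps: int = 10000
    force_tolerance: float = 10.0
    initial_step: float = 0.01  # angstrom

    def __post_init__(self):
        if self.nsteps < 0:
            raise ValueError("nsteps must be non-negative")


def generate_dihedral_restraints(
    ring: RingGeometry, k: float = DEFAULT_RESTRAINT_K
) -> RestraintSet:
    """Phi and psi restraints at their as-built values, wrapping cyclically.

    Residue 1's phi uses the last residue's C; the last residue's psi uses
    residue 1's N.  Deviation is zero: any departure from the as-built
    torsion is penalised.
    """
    if ring.resolution != ATOMISTIC:
        raise GeometryError("RESOLUTION_MISMATCH", "dihedral restraints need an atomistic ring")
    n = ring.sequence.length
    entries = []
    for res in ring.sequence.residues:
        i = res.position
        prev = n if i == 1 else i - 1
        nxt = 1 if i == n else i + 1
        phi = (
            ring.atom_index(prev, "C"),
            ring.atom_index(i, "N"),
            ring.atom_index(i, "CA"),
            ring.atom_index(i, "C"),
        )
        psi = (
            ring.atom_index(i, "N"),
            ring.atom_index(i, "CA"),
            ring.atom_index(i, "C"),
            ring.atom_index(nxt, "N"),
        )
        coords = ring.coordinates()
        for quad in (phi, psi):
            target = np.rad2deg(dihedral(*(coords[j] for j in quad)))
            entries.append(DihedralRestraint(quad, float(target), 0.0, k))
    return RestraintSet(entries)


# ---------------------------------------------------------------------------
# harmonic energy model


@dataclass(frozen=True)
class BondHarmonic:
    i: int
    j: int
    r0: float
    k: float
    kind: str = "bond"  # "bond" for chemical bonds, "aux" for 1-3/1-4 distance terms


@dataclass(frozen=True)
class AngleHarmonic:
    """Cosine-harmonic angle penalty ``k (cos θ − cos θ0)²``.

    The cosine form (GROMACS type-2 / G96 angles) keeps forces bounded as
    θ approaches 180°, which matters here: the flat tentative ring's
    backbone angles sit near 165°, and a plain θ-harmonic gradient
    (∝ 1/sin θ) diverges at linearity and can trap steepest descent."""

    i: int
    j: int
    k_: int
    theta0: float  # radians
    k: float


@dataclass
class HarmonicModel:
    """Sum of harmonic bond/angle penalties plus dihedral restraints."""

    bonds: list[BondHarmonic] = field(default_factory=list)
    angles: list[AngleHarmonic] = field(default_factory=list)
    restraints: RestraintSet = field(default_factory=RestraintSet)

    def validate(self, n_particles: int) -> None:
        for b in self.bonds:
            if not (0 <= b.i < n_particles and 0 <= b.j < n_particles):
                raise TopologyError("BAD_TERM", f"bond ({b.i},{b.j}) out of range")
        for a in self.angles:
            if not all(0 <= x < n_particles for x in (a.i, a.j, a.k_)):
                raise TopologyError("BAD_TERM", f"angle ({a.i},{a.j},{a.k_}) out of range")
        for r in self.restraints.entries:
            if not all(0 <= x < n_particles for x in r.indices):
                raise TopologyError("BAD_TERM", f"restraint {r.indices} out of range")

    def _compile(self, n_particles: int) -> None:
        """Cache vectorised index/parameter arrays for fast evaluation."""
        self._n = n_particles
        b = self.bonds
        self._b_i = np.array([t.i for t in b], dtype=int)
        self._b_j = np.array([t.j for t in b], dtype=int)
        self._b_r0 = np.array([t.r0 for t in b])
        self._b_k = np.array([t.k for t in b])
        a = self.angles
        self._a_i = np.array([t.i for t in a], dtype=int)
        self._a_j = np.array([t.j for t in a], dtype=int)
        self._a_k = np.array([t.k_ for t in a], dtype=int)
        self._a_t0 = np.array([t.theta0 for t in a])
        self._a_kf = np.array([t.k for t in a])
        r = self.restraints.entries
        self._r_idx = np.array([t.indices for t in r], dtype=int).reshape(len(r), 4)
        self._r_phi0 = np.deg2rad(np.array([t.target_deg for t in r]))
        self._r_dev = np.deg2rad(np.array([t.deviation_deg for t in r]))
        self._r_k = np.array([t.k for t in r])

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Total energy and analytic forces (negative gradient), vectorised."""
        signature = (len(coords), len(self.bonds), len(self.angles), len(self.restraints.entries))
        if getattr(self, "_sig", None) != signature:
            self._compile(len(coords))
            self._sig = signature
        energy = 0.0
        forces = np.zeros_like(coords)

        if len(self._b_i):
            d = coords[self._b_i] - coords[self._b_j]
            r = np.linalg.norm(d, axis=1)
            delta = r - self._b_r0
            energy += float(np.sum(self._b_k * delta * delta))
            f = (-2.0 * self._b_k * delta / r)[:, None] * d
            np.add.at(forces, self._b_i, f)
            np.add.at(forces, self._b_j, -f)

        if len(self._a_i):
            u = coords[self._a_i] - coords[self._a_j]
            v = coords[self._a_k] - coords[self._a_j]
            ru = np.linalg.norm(u, axis=1)
            rv = np.linalg.norm(v, axis=1)
            uh = u / ru[:, None]
            vh = v / rv[:, None]
            cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            delta = cos_t - np.cos(self._a_t0)
            energy += float(np.sum(self._a_kf * delta * delta))
            dcos_di = (vh - cos_t[:, None] * uh) / ru[:, None]
            dcos_dk = (uh - cos_t[:, None] * vh) / rv[:, None]
            coeff = (-2.0 * self._a_kf * delta)[:, None]
            np.add.at(forces, self._a_i, coeff * dcos_di)
            np.add.at(forces, self._a_k, coeff * dcos_dk)
            np.add.at(forces, self._a_j, -coeff * (dcos_di + dcos_dk))

        if len(self._r_idx):
            p1, p2, p3, p4 = (coords[self._r_idx[:, m]] for m in range(4))
            b1 = p2 - p1
            b2 = p3 - p2
            b3 = p4 - p3
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            lb2 = np.linalg.norm(b2, axis=1)
            m = np.cross(n1, b2 / lb2[:, None])
            phi = np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))
            diff = np.arctan2(np.sin(phi - self._r_phi0), np.cos(phi - self._r_phi0))
            excess = np.where(
                np.abs(diff) <= self._r_dev, 0.0, diff - np.sign(diff) * self._r_dev
            )
            energy += float(np.sum(0.5 * self._r_k * excess * excess))
            dE = self._r_k * excess
            # signs match the atan2-based torsion convention in _geometry
            # denominators floored: a torsion through three collinear atoms
            # has an undefined gradient; the floor keeps forces finite there
            n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-8)
            n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-8)
            d1 = (lb2 / n1sq)[:, None] * n1
            d4 = (-lb2 / n2sq)[:, None] * n2
            s = (np.sum(b1 * b2, axis=1) / (lb2 * lb2))[:, None]
            t = (np.sum(b3 * b2, axis=1) / (lb2 * lb2))[:, None]
            d2 = -(1.0 + s) * d1 + t * d4
            d3 = s * d1 - (1.0 + t) * d4
            for col, g in enumerate((d1, d2, d3, d4)):
                np.add.at(forces, self._r_idx[:, col], -dE[:, None] * g)
        return energy, forces


def build_regularizer_model(
    ring: RingGeometry,
    restraints: RestraintSet | None = None,
    bond_k: float = DEFAULT_BOND_K,
    angle_k: float = DEFAULT_ANGLE_K,
) -> HarmonicModel:
    """Harmonic terms regularising one atomistic ring.

    Bond targets are the ideal peptide values (backbone N-CA/CA-C/C-N
    cyclic, C=O, N-H, CA-CB); backbone angle targets are the as-built
    values, so regularisation removes jitter without fighting the flat
    tentative layout.
    """
    if ring.resolution != ATOMISTIC:
        raise GeometryError("RESOLUTION_MISMATCH", "regularizer terms need an atomistic ring")
    n = ring.sequence.length
    coords = ring.coordinates()
    bonds: list[BondHarmonic] = []
    angles: list[AngleHarmonic] = []

    def add_bond(i, j, r0):
        bonds.append(BondHarmonic(i, j, r0, bond_k))

    backbone = []
    for res in ring.sequence.residues:
        i = res.position
        backbone.extend(
            [ring.atom_index(i, "N"), ring.atom_index(i, "CA"), ring.atom_index(i, "C")]
        )
    cycle_lengths = [
        DEFAULT_BOND_LENGTHS[("N", "CA")],
        DEFAULT_BOND_LENGTHS[("CA", "C")],
        DEFAULT_BOND_LENGTHS[("C", "N")],
    ] * n
    m = len(backbone)
    for a in range(m):
        add_bond(backbone[a], backbone[(a + 1) % m], cycle_lengths[a])
        trip = (backbone[a], backbone[(a + 1) % m], backbone[(a + 2) % m])
        theta0 = angle_between(coords[trip[0]], coords[trip[1]], coords[trip[2]])
        angles.append(AngleHarmonic(*trip, theta0, angle_k))
        # Auxiliary 1-3 and 1-4 distance terms at their as-built values.
        # Backbone torsions of the near-collinear flat ring are numerically
        # hypersensitive (tiny cross-product lever arms) and the wrapped
        # torsion penalty has a cusp at 180 deg, so a perturbed ring can be
        # steered into a twisted local minimum.  The as-built torsions are
        # essentially 0/180 deg, where the smooth 1-4 distance determines
        # the torsion uniquely; these terms carry the same target geometry
        # without cusps or singularities and keep descent in the flat basin.
        for span, k_aux in ((2, 0.5 * bond_k), (3, 0.25 * bond_k)):
            pair = (backbone[a], backbone[(a + span) % m])
            r0 = float(np.linalg.norm(coords[pair[0]] - coords[pair[1]]))
            bonds.append(BondHarmonic(pair[0], pair[1], r0, k_aux, kind="aux"))

    for res in ring.sequence.residues:
        i = res.position
        add_bond(ring.atom_index(i, "C"), ring.atom_index(i, "O"), CO_LENGTH)
        if ring.find(i, "H") is not None:
            add_bond(ring.atom_index(i, "N"), ring.atom_index(i, "H"), NH_LENGTH)
        if ring.find(i, "CB") is not None:
            add_bond(ring.atom_index(i, "CA"), ring.atom_index(i, "CB"), CA_CB_LENGTH)

    if restraints is None:
        restraints = generate_dihedral_restraints(ring)
    model = HarmonicModel(bonds=bonds, angles=angles, restraints=restraints)
    model.validate(len(ring.atoms))
    return model


def steepest_descent_minimize(
    geometry,
    model: HarmonicModel,
    cfg: MinimizationConfig | None = None,
):
    """Adaptive steepest descent on any object exposing ``coordinates()`` /
    ``set_coordinates()`` (a ring or a nanotube model).

    Returns ``(geometry, trace)`` where the trace lists the energies of the
    initial state and every accepted step (strictly decreasing after the
    first entry).  Stops when the largest per-particle force drops to
    ``force_tolerance``, when ``nsteps`` trials are exhausted, or when the
    step size underflows.
    """
    if cfg is None:
        cfg = MinimizationConfig()
    geometry = geometry.copy()
    coords = geometry.coordinates().astype(float)
    model.validate(len(coords))

    energy, forces = model.energy_forces(coords)
    trace = [energy]
    step = cfg.initial_step
    for _ in range(cfg.nsteps):
        fmax = float(np.max(np.linalg.norm(forces, axis=1)))
        if fmax <= cfg.force_tolerance:
            break
        trial = coords + step * forces / fmax
        trial_energy, trial_forces = model.energy_forces(trial)
        if trial_energy < energy:
            coords, energy, forces = trial, trial_energy, trial_forces
            trace.append(energy)
            step *= 2.0
        else:
            step *= 0.5
            if step < 1e-12:
                break
    geometry.set_coordinates(coords)
    return geometry, trace


def regularize_ring(
    ring: RingGeometry,
    restraints: RestraintSet | None = None,
    cfg: MinimizationConfig | None = None,
    reference: RingGeometry | None = None,
) -> tuple[RingGeometry, tuple[list, list]]:
    """Two-stage regularisation of an atomistic ring.

    Stage 1 minimises the smooth distance-geometry network (bonds, angles
    and the auxiliary 1-3/1-4 terms) without torsion restraints; on the
    near-collinear flat backbone, torsions respond hypersensitively to
    Cartesian noise, and switching the cusped torsion penalties on too
    early can steer a perturbed ring into a twisted local minimum.  Stage 2
    then minimises with the full restraint set, polishing every phi/psi to
    its target.  Both stages use the same steepest-descent engine and each
    energy trace is monotone.

    Angle, auxiliary-distance and torsion targets are measured on
    ``reference`` (defaults to ``ring`` itself, the normal case where the
    as-built tentative geometry is being regularised); pass the clean
    geometry explicitly when minimising a perturbed copy.

    Returns the regularised ring and the pair of traces.
    """
    if cfg is None:
        cfg = MinimizationConfig()
    if reference is None:
        reference = ring
    if restraints is None:
        restraints = generate_dihedral_restraints(reference)
    full = build_regularizer_model(reference, restraints)
    stage1 = HarmonicModel(bonds=full.bonds, angles=full.angles)
    pre_cfg = MinimizationConfig(
        integrator=cfg.integrator,
        nsteps=max(1, cfg.nsteps // 2),
        force_tolerance=cfg.force_tolerance,
        initial_step=cfg.initial_step,
    )
    mid, trace1 = steepest_descent_minimize(ring, stage1, pre_cfg)
    out, trace2 = steepest_descent_minimize(mid, full, cfg)
    return out, (trace1, trace2)


# ---------------------------------------------------------------------------
# GROMACS-dialect writers (round-trippable)


def write_minimization_config(cfg: MinimizationConfig) -> str:
    """Emit run parameters as .mdp-style ``key = value`` text."""
    return (
        "; energy minimisation parameters\n"
        f"integrator  = {cfg.integrator}\n"
        f"nsteps      = {cfg.nsteps}\n"
        f"emtol       = {cfg.force_tolerance:g}\n"
        f"emstep      = {cfg.initial_step:g}\n"
    )


def parse_minimization_config(text: str) -> MinimizationConfig:
    values: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return MinimizationConfig(
        integrator=values.get("integrator", "steep"),
        nsteps=int(values.get("nsteps", "10000")),
        force_tolerance=float(values.get("emtol", "10")),
        initial_step=float(values.get("emstep", "0.01")),
    )


def write_dihedral_restraints(restraints: RestraintSet) -> str:
    """Emit a GROMACS-dialect [dihedral_restraints] section (1-based)."""
    lines = [
        "[ dihedral_restraints ]",
        "; ai  aj  ak  al  type  phi  dphi  kfac",
    ]
    for r in restraints.entries:
        i, j, k, l = (x + 1 for x in r.indices)
        lines.append(
            f"{i:5d} {j:5d} {k:5d} {l:5d}  1  {r.target_deg:10.4f} {r.deviation_deg:8.3f} {r.k:10.3f}"
        )
    return "\n".join(lines) + "\n"


def parse_dihedral_restraints(text: str) -> RestraintSet:
    entries = []
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line or line.startswith("["):
            continue
        parts = line.split()
        i, j, k, l = (int(p) - 1 for p in parts[:4])
        entries.append(
            DihedralRestraint((i, j, k, l), float(parts[5]), float(parts[6]), float(parts[7]))
        )
    return RestraintSet(entries)
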