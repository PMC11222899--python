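"""Cyclic peptide sequences and nanotube designs.

An alpha-D,L cyclic peptide (CP) is written head-to-tail in one-letter code,
the first residue being a D-amino acid and chirality alternating around the
ring.  A flat ring conformation — amide groups perpendicular to the ring
plane — requires an even number of residues; rings of 4 to 12 residues are
supported.  A nanotube design is an ordered stack of such rings, each
interface marked parallel or antiparallel with respect to the ring below.

Glycine has no stereocentre: it is accepted at any position and labelled
``achiral`` while still occupying its positional D or L slot.  Proline is
accepted (its ring nitrogen simply never acts as a hydrogen-bond donor
downstream); a warning is logged because its constrained backbone is a poor
fit for the flat conformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import SequenceError

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

MIN_LENGTH = 4
MAX_LENGTH = 12

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of a cyclic peptide.

    Attributes
    ----------
    code:
        One-letter amino-acid code.
    position:
        1-based index within the ring.
    chirality:
        ``"D"``, ``"L"`` or ``"achiral"`` (glycine only).
    """

    code: str
    position: int
    chirality: str

    def __post_init__(self):
        if self.code not in STANDARD_CODES:
            raise SequenceError("BAD_CODE", f"'{self.code}' is not a standard amino-acid code")
        if (self.chirality == "achiral") != (self.code == "G"):
            raise SequenceError(
                "BAD_CODE", f"chirality '{self.chirality}' inconsistent with code '{self.code}'"
            )


@dataclass(frozen=True)
class CPSequence:
    """A validated cyclic peptide sequence with positional chirality."""

    residues: tuple[ResidueSpec, ...]

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def text(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def chirality_pattern(self) -> tuple[str, ...]:
        return tuple(r.chirality for r in self.residues)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"c-{self.text}"


@dataclass(frozen=True)
class NanotubeDesign:
    """An ordered stack of cyclic peptides with per-interface orientations."""

    sequences: tuple[CPSequence, ...]
    orientations: tuple[str, ...]
    name: str = ""

    @property
    def n_subunits(self) -> int:
        return len(self.sequences)

    @property
    def n_interfaces(self) -> int:
        return len(self.orientations)


def expected_chirality(code: str, position: int) -> str:
    """Chirality a residue must carry at a 1-based ring position.

    Odd positions are D, even positions are L; glycine is achiral anywhere.
    """
    if code == "G":
        return "achiral"
    return "D" if position % 2 == 1 else "L"


def parse_sequence(text: str) -> CPSequence:
    """Parse and validate a one-letter-code cyclic peptide sequence.

    Input is case-insensitive, surrounding whitespace is ignored and an
    optional leading ``c-`` (the conventional prefix marking a cyclic
    peptide, as in ``c-RRKWLWLW``) is stripped.

    Raises
    ------
    SequenceError
        ``ODD_LENGTH`` for an odd residue count, ``LENGTH_RANGE`` outside
        4–12 residues, ``BAD_CODE`` for a non-standard letter.
    """
    if text is None or not text.strip():
        raise SequenceError("BAD_CODE", "empty sequence")
    cleaned = text.strip().upper()
    if cleaned.startswith("C-"):
        cleaned = cleaned[2:]
    for ch in cleaned:
        if ch not in STANDARD_CODES:
            raise SequenceError("BAD_CODE", f"'{ch}' is not a standard one-letter code")
    n = len(cleaned)
    if n % 2 != 0:
        raise SequenceError("ODD_LENGTH", f"{n} residues; a flat D,L-ring needs an even count")
    if not (MIN_LENGTH <= n <= MAX_LENGTH):
        raise SequenceError("LENGTH_RANGE", f"{n} residues; supported ring sizes are {MIN_LENGTH}-{MAX_LENGTH}")
    if "P" in cleaned:
        logger.warning(
            "sequence %s contains proline: its backbone nitrogen carries no amide "
            "hydrogen and is excluded from hydrogen-bond donor lists",
            cleaned,
        )
    residues = tuple(
        ResidueSpec(code=ch, position=i + 1, chirality=expected_chirality(ch, i + 1))
        for i, ch in enumerate(cleaned)
    )
    return CPSequence(residues=residues)


def make_design(
    sequence_texts: list[str],
    orientation_texts: list[str],
    name: str = "",
) -> NanotubeDesign:
    """Validate a nanotube design: one sequence per subunit plus one
    parallel/antiparallel flag per inter-ring interface.

    Raises
    ------
    SequenceError
        ``ORIENTATION_COUNT`` when the number of orientations is not
        ``len(sequences) - 1``; ``LENGTH_MISMATCH`` when subunit sequences
        differ in length (rings of unequal size cannot stack in registry);
        plus any :func:`parse_sequence` error.
    """
    if not sequence_texts:
        raise SequenceError("ORIENTATION_COUNT", "a design needs at least one sequence")
    sequences = tuple(parse_sequence(t) for t in sequence_texts)
    orientations = []
    for t in orientation_texts:
        o = t.strip().lower()
        if o not in (PARALLEL, ANTIPARALLEL):
            raise SequenceError(
                "ORIENTATION_COUNT", f"orientation '{t}' must be parallel or antiparallel"
            )
        orientations.append(o)
    if len(orientations) != len(sequences) - 1:
        raise SequenceError(
            "ORIENTATION_COUNT",
            f"{len(sequences)} subunits need {len(sequences) - 1} orientations, got {len(orientations)}",
        )
    lengths = {s.length for s in sequences}
    if len(lengths) > 1:
        raise SequenceError(
            "LENGTH_MISMATCH", f"all subunits must share one ring size, got {sorted(lengths)}"
        )
    return NanotubeDesign(sequences=sequences, orientations=tuple(orientations), name=name)
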