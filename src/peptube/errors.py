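"""Error types raised across the build pipeline.

Every error carries a short machine-readable ``code`` so callers (and the
command line) can report a stable single-line diagnostic.
"""

from __future__ import annotations


class PeptubeError(Exception):
    """Base class for all builder errors.

    Parameters
    ----------
    code:
        Stable identifier such as ``ODD_LENGTH`` or ``UNKNOWN_PROFILE``.
    message:
        Human-readable description.
    """

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code
        self.message = message


class SequenceError(PeptubeError):
    """Invalid peptide sequence or nanotube design."""


class GeometryError(PeptubeError):
    """Missing or inconsistent structural data."""


class TopologyError(PeptubeError):
    """Invalid bonded-topology input or parameters."""


class FormatError(PeptubeError):
    """File reading/writing failure (carries a line number when parsing)."""

    def __init__(self, code: str, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(code, message)
        self.line = line


class ProfileError(PeptubeError):
    """Unknown or unusable force-field profile."""
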