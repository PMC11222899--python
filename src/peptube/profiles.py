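"""Named force-field profiles.

A profile fixes the resolution (atomistic vs coarse-grain) and points at
the data the topology stage needs: linear topology templates for atomistic
profiles (the pdb2gmx-style input that gets cyclized) or a bead mapping
plus bonded-parameter table for coarse ones.  The ten canonical names
cover the published Amber/OPLS/CHARMM and MARTINI/MA(R/S)TINI families;
their parameter sets are external data the user supplies.  Two fixture
profiles ship toy data so the full pipeline is runnable and testable
without downloads.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import ProfileError

_REGISTRY_CACHE: list[dict] | None = None


@dataclass(frozen=True)
class ForceFieldProfile:
    name: str
    resolution: str  # "atomistic" | "coarse"
    canonical: bool = True
    mapping_file: str | None = None
    params_file: str | None = None
    template_files: dict[str, str] = field(default_factory=dict)
    internal_charges: dict[str, float] = field(default_factory=dict)

    @property
    def data_missing(self) -> bool:
        if self.resolution == "coarse":
            return self.mapping_file is None or self.params_file is None
        return not self.template_files

    def load_mapping(self) -> dict:
        if self.mapping_file is None:
            raise ProfileError("UNKNOWN_PROFILE", f"profile {self.name} has no mapping table")
        ref = importlib.resources.files("peptube.data") / self.mapping_file
        return yaml.safe_load(ref.read_text())

    def load_params(self) -> dict:
        if self.params_file is None:
            raise ProfileError("UNKNOWN_PROFILE", f"profile {self.name} has no parameter table")
        ref = importlib.resources.files("peptube.data") / self.params_file
        return yaml.safe_load(ref.read_text())

    def load_linear_template_text(self, sequence_text: str) -> str:
        path = self.template_files.get(sequence_text)
        if path is None:
            raise ProfileError(
                "UNKNOWN_PROFILE",
                f"profile {self.name} ships no linear topology for {sequence_text}; "
                "supply one (pdb2gmx output) via the template option",
            )
        ref = importlib.resources.files("peptube.data") / path
        return ref.read_text()


def _registry() -> list[dict]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        ref = importlib.resources.files("peptube.data") / "profiles.yaml"
        _REGISTRY_CACHE = yaml.safe_load(ref.read_text())["profiles"]
    return _REGISTRY_CACHE


def _normalise(name: str) -> str:
    out = []
    for ch in name.lower():
        if ch.isalnum() or ch == ".":
            out.append(ch)
    return "".join(out)


def list_profiles(canonical_only: bool = False) -> list[str]:
    return [
        e["name"] for e in _registry() if e.get("canonical", True) or not canonical_only
    ]


def resolve_profile(name: str) -> ForceFieldProfile:
    """Look up a profile, tolerating case/spacing/punctuation variants
    ("MARTINI 2.2", "martini2.2" and "MA(R/S)TINI" all resolve)."""
    wanted = _normalise(name)
    for entry in _registry():
        if _normalise(entry["name"]) == wanted:
            return ForceFieldProfile(
                name=entry["name"],
                resolution=entry["resolution"],
                canonical=entry.get("canonical", True),
                mapping_file=entry.get("mapping"),
                params_file=entry.get("params"),
                template_files=entry.get("templates", {}) or {},
                internal_charges=entry.get("internal_charges", {}) or {},
            )
    raise ProfileError("UNKNOWN_PROFILE", f"no force-field profile named '{name}'")
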