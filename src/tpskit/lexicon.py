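"""Loaders for the two package lexicons.

``CompoundLexicon`` maps GC-MS compound names to their class (monoterpene,
sesquiterpene, internal_standard or non_terpene), putative-identification flag
and fixed reference retention time.  ``ChemicalLexicon`` maps crystallisation
chemicals (buffers, salts, precipitants) to canonical names and default roles,
with a synonym table for free-text parsing.

Lookups are case-insensitive; hyphens and repeated whitespace are collapsed,
and spelled-out Greek prefixes (``alpha-`` …) are folded to their letters so
that e.g. ``beta-myrcene`` resolves to ``β-myrcene``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

import yaml

_GREEK = {
    "alpha-": "α-", "beta-": "β-", "gamma-": "γ-", "delta-": "δ-",
    "epsilon-": "ε-",
}


def normalise_name(name: str) -> str:
    """Canonicalise a chemical/compound name for lookup."""
    s = name.strip().lower()
    for ascii_, greek in _GREEK.items():
        s = s.replace(ascii_, greek)
    s = s.replace("-", " ")
    s = re.sub(r"\s+", " ", s)
    return s


@dataclass(frozen=True)
class CompoundEntry:
    name: str
    klass: str  # monoterpene | sesquiterpene | internal_standard | non_terpene
    rt_min: float
    putative: bool
    alias_of: str | None = None


@dataclass
class CompoundLexicon:
    entries: dict[str, CompoundEntry]
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, entry in self.entries.items():
            self._index[normalise_name(name)] = name

    def get(self, name: str) -> CompoundEntry | None:
        canonical = self._index.get(normalise_name(name))
        return self.entries[canonical] if canonical else None

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    def rt_of(self, name: str) -> float:
        entry = self.get(name)
        if entry is None:
            raise KeyError(name)
        return entry.rt_min


@dataclass(frozen=True)
class ChemicalEntry:
    name: str
    role: str  # buffer | salt | precipitant
    synonyms: tuple[str, ...] = ()


@dataclass
class ChemicalLexicon:
    entries: dict[str, ChemicalEntry]
    ammonium_sulfate_threshold_M: float = 0.8
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, entry in self.entries.items():
            self._index[normalise_name(name)] = name
            for syn in entry.synonyms:
                self._index[normalise_name(syn)] = name

    def get(self, name: str) -> ChemicalEntry | None:
        canonical = self._index.get(normalise_name(name))
        return self.entries[canonical] if canonical else None

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    def role_of(self, name: str, concentration_M: float | None = None) -> str:
        """Default role, with the ammonium-sulfate concentration override."""
        entry = self.get(name)
        if entry is None:
            return "other"
        if (
            entry.name == "ammonium sulfate"
            and concentration_M is not None
            and concentration_M >= self.ammonium_sulfate_threshold_M
        ):
            return "precipitant"
        return entry.role

    def names_with_role(self, role: str) -> list[str]:
        return [n for n, e in self.entries.items() if e.role == role]

    def is_peg(self, name: str) -> bool:
        entry = self.get(name)
        return entry is not None and entry.name.startswith("PEG")


def _read_yaml(filename: str) -> dict:
    text = resources.files("tpskit.data").joinpath(filename).read_text("utf-8")
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def load_compound_lexicon() -> CompoundLexicon:
    raw = _read_yaml("compounds.yaml")
    entries = {}
    for name, spec in raw["compounds"].items():
        entries[name] = CompoundEntry(
            name=name,
            klass=spec["class"],
            rt_min=float(spec["rt_min"]),
            putative=bool(spec["putative"]),
            alias_of=spec.get("alias_of"),
        )
    lex = CompoundLexicon(entries)
    for name, spec in raw["compounds"].items():
        for syn in spec.get("synonyms", []):
            lex._index[normalise_name(syn)] = name
    return lex


@lru_cache(maxsize=1)
def load_chemical_lexicon() -> ChemicalLexicon:
    raw = _read_yaml("chemicals.yaml")
    entries = {}
    for name, spec in raw["chemicals"].items():
        entries[name] = ChemicalEntry(
            name=name,
            role=spec["role"],
            synonyms=tuple(spec.get("synonyms", [])),
        )
    return ChemicalLexicon(
        entries,
        ammonium_sulfate_threshold_M=float(
            raw.get("ammonium_sulfate_precipitant_threshold_M", 0.8)
        ),
    )
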