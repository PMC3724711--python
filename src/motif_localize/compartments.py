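"""Controlled vocabulary of subcellular compartments.

Localization is assigned to proteins purely from Swiss-Prot keywords: each
keyword in the vocabulary maps to exactly one compartment code, and a protein
receives the union of the codes of its keywords.  Matching is exact and
case-sensitive on whole keywords, so the specific keyword ``Cell membrane``
maps to the plasma membrane while the generic ``Membrane`` keyword (which
marks any membrane association, including organelle membranes) maps to
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

__all__ = [
    "VocabularyEntry",
    "CompartmentVocabulary",
    "keywords_to_localizations",
    "TWELVE_COMPARTMENTS",
    "DEFAULT_SEVEN_CODES",
]

#: The twelve-compartment vocabulary: (Swiss-Prot keyword, compartment name,
#: three-letter code).  Order is meaningful and is preserved in all outputs.
TWELVE_COMPARTMENTS: tuple[tuple[str, str, str], ...] = (
    ("Cytoplasm", "Cytosol", "cyt"),
    ("Chloroplast", "Chloroplast", "chl"),
    ("Secreted", "Extracellular", "ext"),
    ("Cell membrane", "C_Membrane", "Mem"),
    ("Mitochondrion", "Mitochondrion", "Mit"),
    ("Nucleus", "Nucleus", "Nuc"),
    ("Periplasm", "Periplasm", "Per"),
    ("Endoplasmic reticulum", "E_Reticulum", "Ret"),
    ("Golgi apparatus", "Golgi", "Gol"),
    ("Peroxisome", "Peroxisome", "Prx"),
    ("Lysosome", "Lysosome", "Lys"),
    ("Vacuole", "Vacuole", "Vac"),
)

#: Default subset used in seven-compartment mode (configurable; the reduced
#: mode keeps the seven most populated compartments, i.e. the first seven of
#: the ordered vocabulary).
DEFAULT_SEVEN_CODES: tuple[str, ...] = ("cyt", "chl", "ext", "Mem", "Mit", "Nuc", "Per")


@dataclass(frozen=True)
class VocabularyEntry:
    """One keyword-to-compartment mapping."""

    keyword: str
    compartment_name: str
    code: str


@dataclass(frozen=True)
class CompartmentVocabulary:
    """Ordered set of compartments plus the keyword map that populates them.

    Parameters
    ----------
    entries
        Ordered vocabulary entries.  Several keywords may map to the same
        code (useful for user-supplied extensions); codes keep the order of
        their first appearance.
    mode
        ``"twelve"``, ``"seven"`` or ``"custom"``; informational.
    """

    entries: tuple[VocabularyEntry, ...]
    mode: str = "twelve"
    _keyword_map: Mapping[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen_keywords: dict[str, str] = {}
        for e in self.entries:
            if not e.keyword or not e.code:
                raise ValueError("vocabulary entries need non-empty keyword and code")
            if e.keyword in seen_keywords and seen_keywords[e.keyword] != e.code:
                raise ValueError(f"keyword {e.keyword!r} maps to two different codes")
            seen_keywords[e.keyword] = e.code
        object.__setattr__(self, "_keyword_map", seen_keywords)

    @classmethod
    def default(cls, mode: str = "twelve", seven_codes: Sequence[str] = DEFAULT_SEVEN_CODES) -> "CompartmentVocabulary":
        """The standard vocabulary in ``twelve`` or ``seven`` mode."""
        entries = tuple(VocabularyEntry(*row) for row in TWELVE_COMPARTMENTS)
        if mode == "twelve":
            return cls(entries=entries, mode="twelve")
        if mode == "seven":
            keep = set(seven_codes)
            unknown = keep - {e.code for e in entries}
            if unknown:
                raise ValueError(f"unknown compartment codes for seven mode: {sorted(unknown)}")
            return cls(entries=tuple(e for e in entries if e.code in keep), mode="seven")
        raise ValueError(f"mode must be 'twelve' or 'seven', got {mode!r}")

    @classmethod
    def from_table(cls, source: str | Path | TextIO, mode: str = "custom") -> "CompartmentVocabulary":
        """Load a vocabulary from a two- or three-column TAB-separated file.

        Columns: keyword, code[, compartment name].  Lines starting with
        ``#`` and blank lines are ignored.
        """
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as fh:
                return cls.from_table(fh, mode=mode)
        entries = []
        for lineno, raw in enumerate(source, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'keyword<TAB>code', got {line!r}")
            keyword, code = parts[0], parts[1]
            name = parts[2] if len(parts) > 2 and parts[2] else code
            entries.append(VocabularyEntry(keyword=keyword, compartment_name=name, code=code))
        return cls(entries=tuple(entries), mode=mode)

    @property
    def codes(self) -> tuple[str, ...]:
        """Compartment codes in vocabulary order (first appearance)."""
        out: list[str] = []
        for e in self.entries:
            if e.code not in out:
                out.append(e.code)
        return tuple(out)

    @property
    def keyword_map(self) -> Mapping[str, str]:
        return dict(self._keyword_map)

    def name_of(self, code: str) -> str:
        for e in self.entries:
            if e.code == code:
                return e.compartment_name
        raise KeyError(code)

    def __contains__(self, code: str) -> bool:
        return any(e.code == code for e in self.entries)


def keywords_to_localizations(keywords: Iterable[str], vocab: CompartmentVocabulary) -> frozenset[str]:
    """Map a set of Swiss-Prot keywords to compartment codes.

    Matching is exact (whole keyword, case-sensitive); keywords outside the
    vocabulary are silently ignored.
    """
    kmap = vocab._keyword_map
    return frozenset(kmap[kw] for kw in keywords if kw in kmap)
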