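"""Swiss-Prot flat-file input and localization datasets.

Only the record fields needed for keyword-based localization are kept:
accessions (AC), entry name (ID) and keywords (KW).  The flat file is
chunked on ``//`` terminators here (so that errors can name a line offset
and documentation-free tolerance is explicit) and each record body is parsed
with Biopython's :mod:`Bio.SwissProt` reader.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
from Bio import SwissProt

from .compartments import CompartmentVocabulary, keywords_to_localizations

__all__ = [
    "ProteinRecord",
    "LocalizationDataset",
    "SwissProtParseError",
    "parse_swissprot",
    "build_alias_index",
    "build_dataset",
    "restrict_single",
    "dataset_frequencies",
    "write_mapping",
]


class SwissProtParseError(ValueError):
    """Malformed Swiss-Prot record; the message names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """A Swiss-Prot entry reduced to accession(s), name and keywords."""

    primary_accession: str
    entry_name: str
    keywords: frozenset[str]
    secondary_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.primary_accession:
            raise ValueError("primary_accession must be non-empty")


def _open_text(source: str | Path | IO) -> IO:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
        return open(path, encoding="utf-8")
    return source


def _iter_record_chunks(stream: IO) -> Iterator[tuple[int, list[str]]]:
    """Yield (first line number, record lines incl. '//') per record."""
    lines: list[str] = []
    start = 1
    for lineno, raw in enumerate(stream, start=1):
        if not lines:
            start = lineno
        lines.append(raw)
        if raw.rstrip("\n") == "//":
            yield start, lines
            lines = []
    if any(line.strip() for line in lines):
        raise SwissProtParseError(
            f"line {start}: record starting here is not terminated by '//'"
        )


def _strip_evidence(keyword: str) -> str:
    # Later UniProt releases append evidence tags such as "{ECO:...}".
    brace = keyword.find("{")
    if brace != -1:
        keyword = keyword[:brace]
    return keyword.strip()


def parse_swissprot(source: str | Path | IO) -> list[ProteinRecord]:
    """Parse a UniProtKB/Swiss-Prot flat file (plain or gzip).

    Returns one :class:`ProteinRecord` per entry.  Raises
    :class:`SwissProtParseError` when a record lacks an AC line before its
    ``//`` terminator, naming the line offset of the record.
    """
    stream = _open_text(source)
    close = isinstance(source, (str, Path))
    records: list[ProteinRecord] = []
    try:
        for start, lines in _iter_record_chunks(stream):
            if not any(line.startswith("AC   ") for line in lines):
                raise SwissProtParseError(
                    f"line {start}: record starting here has no AC line before '//'"
                )
            try:
                rec = SwissProt.read(io.StringIO("".join(lines)))
            except Exception as exc:  # re-raise with location information
                raise SwissProtParseError(f"line {start}: {exc}") from exc
            keywords = frozenset(
                kw for kw in (_strip_evidence(k) for k in rec.keywords) if kw
            )
            records.append(
                ProteinRecord(
                    primary_accession=rec.accessions[0],
                    entry_name=rec.entry_name,
                    keywords=keywords,
                    secondary_accessions=tuple(rec.accessions[1:]),
                )
            )
    finally:
        if close:
            stream.close()
    return records


def build_alias_index(records: Iterable[ProteinRecord]) -> dict[str, str]:
    """Map every accession (primary or secondary) to its primary accession.

    PROSITE cross-references may cite accessions that were later merged into
    another entry; resolving through this index joins them correctly.
    """
    index: dict[str, str] = {}
    for rec in records:
        index[rec.primary_accession] = rec.primary_accession
        for alias in rec.secondary_accessions:
            index.setdefault(alias, rec.primary_accession)
    return index


@dataclass(frozen=True)
class LocalizationDataset:
    """Accession -> compartment codes, with database-wide background counts.

    ``N`` is the number of proteins carrying at least one compartment (the
    enrichment universe) and ``K[c]`` the number of those carrying
    compartment ``c``; proteins without any mapped localization keyword are
    not part of the universe.
    """

    assignments: Mapping[str, frozenset[str]]
    vocab: CompartmentVocabulary
    mode: str = "multiple"  # "multiple" | "single_only"
    N: int = field(init=False)
    K: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for acc, codes in self.assignments.items():
            if not codes:
                raise ValueError(f"{acc}: empty compartment set in dataset")
            if self.mode == "single_only" and len(codes) != 1:
                raise ValueError(f"{acc}: multi-compartment entry in single_only dataset")
        K = {c: 0 for c in self.vocab.codes}
        for codes in self.assignments.values():
            for c in codes:
                K[c] += 1
        object.__setattr__(self, "N", len(self.assignments))
        object.__setattr__(self, "K", K)

    def __contains__(self, accession: str) -> bool:
        return accession in self.assignments

    def multi_count(self) -> int:
        """Number of proteins assigned to two or more compartments."""
        return sum(1 for codes in self.assignments.values() if len(codes) >= 2)


def build_dataset(
    records: Iterable[ProteinRecord], vocab: CompartmentVocabulary
) -> LocalizationDataset:
    """Assign compartments to every protein whose keywords map to >= 1 code."""
    assignments: dict[str, frozenset[str]] = {}
    for rec in records:
        codes = keywords_to_localizations(rec.keywords, vocab)
        if codes:
            assignments[rec.primary_accession] = codes
    return LocalizationDataset(assignments=assignments, vocab=vocab, mode="multiple")


def restrict_single(ds: LocalizationDataset) -> LocalizationDataset:
    """Keep only proteins with exactly one assigned compartment."""
    if ds.mode != "multiple":
        raise ValueError("restrict_single expects a dataset in 'multiple' mode")
    assignments = {a: c for a, c in ds.assignments.items() if len(c) == 1}
    return LocalizationDataset(assignments=assignments, vocab=ds.vocab, mode="single_only")


def dataset_frequencies(ds: LocalizationDataset) -> pd.DataFrame:
    """Per-compartment counts/percentages plus the multi-localization summary.

    Rows are compartment codes (vocabulary order) followed by a ``Multiple``
    row counting proteins with several localizations.  ``multi_count`` /
    ``multi_fraction`` give, per compartment, how many of its proteins are
    multi-compartmental.
    """
    N = ds.N
    multi = ds.multi_count()
    rows = []
    for c in ds.vocab.codes:
        k = ds.K[c]
        multi_c = sum(
            1 for codes in ds.assignments.values() if c in codes and len(codes) >= 2
        )
        rows.append(
            {
                "compartment": c,
                "count": k,
                "percent": 100.0 * k / N if N else 0.0,
                "multi_count": multi_c,
                "multi_fraction": multi_c / k if k else 0.0,
            }
        )
    rows.append(
        {
            "compartment": "Multiple",
            "count": multi,
            "percent": 100.0 * multi / N if N else 0.0,
            "multi_count": multi,
            "multi_fraction": 1.0 if multi else 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("compartment")


def write_mapping(ds: LocalizationDataset, path: str | Path) -> None:
    """Write the accession -> localization table (TSV, codes comma-separated)."""
    order = {c: i for i, c in enumerate(ds.vocab.codes)}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for acc in sorted(ds.assignments):
            codes = sorted(ds.assignments[acc], key=order.__getitem__)
            fh.write(f"{acc}\t{','.join(codes)}\n")
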