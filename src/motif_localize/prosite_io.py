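"""PROSITE flat-file (prosite.dat dialect) motif input.

Each motif record carries, besides its descriptor (pattern consensus or
scoring matrix), the curated lists of Swiss-Prot matches on its DR lines,
flagged ``T`` (true positive), ``F`` (false positive), ``N`` (false
negative), ``P`` (potential) or ``?`` (unknown).  Only the T and F sets are
retained as sets of protein accessions; the other flags are parsed and
ignored.  The analysis never evaluates motifs against sequences — PROSITE's
own curated hit lists are the data.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Mapping

__all__ = ["MotifRecord", "PrositeParseError", "parse_prosite"]

_KNOWN_FLAGS = {"T", "F", "N", "P", "?"}


class PrositeParseError(ValueError):
    """Malformed PROSITE record; the message names the offending line."""


@dataclass(frozen=True)
class MotifRecord:
    """One PROSITE motif with its curated true/false-positive hit sets."""

    accession: str
    name: str
    kind: str  # "pattern" | "matrix"
    description: str = ""
    consensus: str = ""
    tp_accessions: frozenset[str] = frozenset()
    fp_accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("pattern", "matrix"):
            raise ValueError(f"kind must be 'pattern' or 'matrix', got {self.kind!r}")
        if self.tp_accessions & self.fp_accessions:
            raise ValueError(
                f"{self.accession}: accessions flagged both T and F: "
                f"{sorted(self.tp_accessions & self.fp_accessions)}"
            )


def _open_text(source: str | Path | IO) -> IO:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
        return open(path, encoding="utf-8")
    return source


def _iter_record_chunks(stream: IO) -> Iterator[tuple[int, list[str]]]:
    lines: list[str] = []
    start = 1
    for lineno, raw in enumerate(stream, start=1):
        if not lines:
            start = lineno
        lines.append(raw.rstrip("\n"))
        if lines[-1] == "//":
            yield start, lines
            lines = []
    # trailing non-record text (copyright banner etc.) is tolerated


def _parse_dr_line(
    payload: str, accession: str, lineno: int
) -> Iterator[tuple[str, str]]:
    """Yield (protein accession, flag) for each triplet on one DR line."""
    for triplet in payload.split(";"):
        triplet = triplet.strip()
        if not triplet:
            continue
        parts = [p.strip() for p in triplet.split(",")]
        if len(parts) != 3 or parts[2] not in _KNOWN_FLAGS:
            warnings.warn(
                f"{accession}: line {lineno}: skipping DR triplet {triplet!r} "
                "(unknown flag or malformed)",
                stacklevel=2,
            )
            continue
        yield parts[0], parts[2]


def parse_prosite(
    source: str | Path | IO, alias_index: Mapping[str, str] | None = None
) -> list[MotifRecord]:
    """Parse a prosite.dat flat file (plain or gzip) into motif records.

    Records without an ID line (documentation-only blocks) are skipped; a
    record with an ID but no AC line is an error.  When ``alias_index`` is
    given, DR accessions are resolved through it (secondary -> primary);
    accessions absent from the index are kept as-is.
    """
    stream = _open_text(source)
    close = isinstance(source, (str, Path))
    motifs: list[MotifRecord] = []
    try:
        for start, lines in _iter_record_chunks(stream):
            id_line = next((l for l in lines if l.startswith("ID   ")), None)
            if id_line is None:
                continue
            payload = id_line[5:].rstrip(".")
            try:
                name, type_token = (p.strip() for p in payload.split(";"))
            except ValueError:
                raise PrositeParseError(f"line {start}: malformed ID line {id_line!r}")
            kind = {"PATTERN": "pattern", "MATRIX": "matrix"}.get(type_token)
            if kind is None:
                raise PrositeParseError(
                    f"line {start}: unknown motif type {type_token!r}"
                )
            ac_line = next((l for l in lines if l.startswith("AC   ")), None)
            if ac_line is None:
                raise PrositeParseError(
                    f"line {start}: record {name!r} has no AC line"
                )
            accession = ac_line[5:].strip().rstrip(";")
            description = " ".join(
                l[5:].strip() for l in lines if l.startswith("DE   ")
            ).rstrip(".")
            consensus = "".join(
                l[5:].strip() for l in lines if l.startswith("PA   ")
            ).rstrip(".")
            flagged: dict[str, set[str]] = {f: set() for f in _KNOWN_FLAGS}
            for offset, line in enumerate(lines):
                if line.startswith("DR   "):
                    for acc, flag in _parse_dr_line(line[5:], accession, start + offset):
                        if alias_index is not None:
                            acc = alias_index.get(acc, acc)
                        flagged[flag].add(acc)
            motifs.append(
                MotifRecord(
                    accession=accession,
                    name=name,
                    kind=kind,
                    description=description,
                    consensus=consensus,
                    tp_accessions=frozenset(flagged["T"]),
                    fp_accessions=frozenset(flagged["F"]),
                )
            )
    finally:
        if close:
            stream.close()
    return motifs
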