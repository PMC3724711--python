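"""Keyword structure of false-positive groups.

When a motif's FP set is significantly enriched in some compartment, the
Swiss-Prot keywords of the FP proteins assigned there often reveal what
those proteins have in common (e.g. all transmembrane).  This module counts
keywords across such FP groups, after removing bookkeeping keywords that
carry no biology (technical terms and coding-sequence-diversity terms).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .enrichment import EnrichmentResult
from .prosite_io import MotifRecord
from .sprot_io import LocalizationDataset, ProteinRecord

__all__ = [
    "DEFAULT_EXCLUDED_KEYWORDS",
    "KeywordCount",
    "FPKeywordReport",
    "fp_keyword_frequencies",
]

#: Keywords removed before counting: the "Technical term" group and the
#: "Coding sequence diversity" group.
DEFAULT_EXCLUDED_KEYWORDS: frozenset[str] = frozenset(
    {"3D-structure", "Reference proteome", "Complete proteome", "Alternative splicing"}
)


@dataclass(frozen=True)
class KeywordCount:
    keyword: str
    count: int
    group_size: int

    def __post_init__(self) -> None:
        if not (2 <= self.count <= self.group_size):
            raise ValueError("retained keywords must satisfy 2 <= count <= group_size")


@dataclass(frozen=True)
class FPKeywordReport:
    """Keyword frequencies for one group of FP proteins.

    ``group_codes`` is the set of significant FP compartments defining the
    group (all of them when pooled, one when split per compartment);
    ``reason`` explains an empty result.
    """

    motif_accession: str
    group_codes: frozenset[str]
    group_size: int
    counts: tuple[KeywordCount, ...]
    reason: str | None = None


def _count_group(
    motif: MotifRecord,
    members: list[ProteinRecord],
    group_codes: frozenset[str],
    exclusions: frozenset[str],
) -> FPKeywordReport:
    tally: Counter[str] = Counter()
    for rec in members:
        tally.update(rec.keywords - exclusions)
    counts = tuple(
        KeywordCount(keyword=kw, count=c, group_size=len(members))
        for kw, c in sorted(tally.items(), key=lambda it: (-it[1], it[0]))
        if c > 1
    )
    return FPKeywordReport(
        motif_accession=motif.accession,
        group_codes=group_codes,
        group_size=len(members),
        counts=counts,
    )


def fp_keyword_frequencies(
    motif: MotifRecord,
    records: Mapping[str, ProteinRecord],
    fp_enrichment: EnrichmentResult,
    ds: LocalizationDataset,
    exclusions: Iterable[str] = DEFAULT_EXCLUDED_KEYWORDS,
    per_compartment: bool = False,
) -> list[FPKeywordReport]:
    """Count keywords over the FP proteins in significant FP compartments.

    The group pools all significant compartments by default; with
    ``per_compartment`` one report is produced per significant compartment.
    Keywords in ``exclusions`` are removed and only keywords occurring more
    than once are retained, sorted by count descending then alphabetically.
    """
    exclusions = frozenset(exclusions)
    significant = fp_enrichment.enriched_codes
    if not significant:
        return [
            FPKeywordReport(
                motif_accession=motif.accession,
                group_codes=frozenset(),
                group_size=0,
                counts=(),
                reason="no significant FP compartment",
            )
        ]
    groups = (
        [frozenset({c}) for c in sorted(significant)]
        if per_compartment
        else [frozenset(significant)]
    )
    reports = []
    for group_codes in groups:
        members = [
            records[acc]
            for acc in sorted(motif.fp_accessions)
            if acc in records and ds.assignments.get(acc, frozenset()) & group_codes
        ]
        reports.append(_count_group(motif, members, group_codes, exclusions))
    return reports
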