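"""Pipeline orchestration and the three report surfaces.

``run_pipeline`` ties the modules together: parse the protein database,
build the localization dataset (all proteins or single-localization only),
parse the motif collection, and for every motif compute compartment
enrichment of its TP and FP sets, its category, its heterogeneity test and
its compartment assignment.  Results are written as

* ``<prefix>.mapping``     protein accession -> comma-separated compartments
* ``<prefix>.tables``      one block per motif: per-compartment TP/FP counts
                           with significance asterisks, category, Fisher p
* ``<prefix>.statistics``  dataset frequencies, coverage by motif kind,
                           category counts, assignment-size histogram,
                           Fisher summary, pair matrix and combination tables

plus a JSON mirror of the statistics and a run manifest (input checksums,
version, parameters).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

from tqdm.auto import tqdm

from . import __version__
from .compartments import CompartmentVocabulary
from .cooccurrence import (ComboTable, PairMatrix, assignment_size_histogram,
                           combo_table, pair_matrix)
from .enrichment import (DEFAULT_ALPHA, EnrichmentResult, MotifCategory,
                         SetLocalizationCounts, classify_motif, count_set,
                         enrich_set)
from .heterogeneity import FisherOutcome, test_motif
from .prosite_io import MotifRecord, parse_prosite
from .sprot_io import (LocalizationDataset, build_alias_index, build_dataset,
                       parse_swissprot, dataset_frequencies, restrict_single,
                       write_mapping)

logger = logging.getLogger(__name__)

__all__ = ["MotifReport", "PipelineResult", "analyze_motifs", "run_pipeline"]

MAX_COMBO_K = 5


@dataclass(frozen=True)
class MotifReport:
    """All computed results for one motif."""

    motif: MotifRecord
    category: MotifCategory
    tp_counts: SetLocalizationCounts
    fp_counts: SetLocalizationCounts
    tp_enrichment: EnrichmentResult | None
    fp_enrichment: EnrichmentResult | None
    fisher: FisherOutcome | None
    assigned: frozenset[str] | None  # None when no localized TP protein


@dataclass(frozen=True)
class PipelineResult:
    vocab: CompartmentVocabulary
    dataset: LocalizationDataset
    reports: tuple[MotifReport, ...]
    pair: PairMatrix
    combos: Mapping[int, ComboTable]

    @property
    def category_counts(self) -> dict[MotifCategory, int]:
        counts = {cat: 0 for cat in MotifCategory}
        for r in self.reports:
            counts[r.category] += 1
        return counts

    @property
    def assignments(self) -> dict[str, frozenset[str]]:
        return {
            r.motif.accession: r.assigned
            for r in self.reports
            if r.assigned is not None
        }

    @property
    def assignment_histogram(self) -> dict[int, int]:
        return assignment_size_histogram(self.assignments)

    @property
    def fisher_tested(self) -> int:
        return sum(1 for r in self.reports if r.fisher and r.fisher.p_value is not None)

    @property
    def fisher_significant(self) -> int:
        return sum(1 for r in self.reports if r.fisher and r.fisher.significant)

    def coverage_by_kind(self) -> dict[str, dict[str, int]]:
        """Motif counts and TP/FP set sizes (total and localized) per kind."""
        out: dict[str, dict[str, int]] = {}
        for kind in ("matrix", "pattern"):
            rows = [r for r in self.reports if r.motif.kind == kind]
            out[kind] = {
                "motifs": len(rows),
                "tp_total": sum(r.tp_counts.n_total for r in rows),
                "tp_localized": sum(r.tp_counts.n for r in rows),
                "fp_total": sum(r.fp_counts.n_total for r in rows),
                "fp_localized": sum(r.fp_counts.n for r in rows),
            }
        out["total"] = {
            key: out["matrix"][key] + out["pattern"][key] for key in out["matrix"]
        }
        return out


def analyze_motifs(
    motifs: list[MotifRecord],
    ds: LocalizationDataset,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
    progress: bool = False,
) -> PipelineResult:
    """Run enrichment, classification, assignment and Fisher testing."""
    reports: list[MotifReport] = []
    iterator = tqdm(motifs, desc="motifs", disable=not progress)
    for motif in iterator:
        tp_counts = count_set(motif.tp_accessions, ds)
        fp_counts = count_set(motif.fp_accessions, ds)
        category = classify_motif(motif, ds)
        tp_enr = (
            enrich_set(tp_counts, ds, alpha=alpha, correction=correction)
            if tp_counts.n
            else None
        )
        fp_enr = (
            enrich_set(fp_counts, ds, alpha=alpha, correction=correction)
            if fp_counts.n
            else None
        )
        fisher = (
            test_motif(motif, ds, alpha=alpha)
            if category is MotifCategory.TESTABLE
            else None
        )
        assigned = tp_enr.enriched_codes if tp_enr is not None else None
        reports.append(
            MotifReport(
                motif=motif,
                category=category,
                tp_counts=tp_counts,
                fp_counts=fp_counts,
                tp_enrichment=tp_enr,
                fp_enrichment=fp_enr,
                fisher=fisher,
                assigned=assigned,
            )
        )
    assignments = {
        r.motif.accession: r.assigned for r in reports if r.assigned is not None
    }
    combos = {k: combo_table(assignments, k) for k in range(3, MAX_COMBO_K + 1)}
    return PipelineResult(
        vocab=ds.vocab,
        dataset=ds,
        reports=tuple(reports),
        pair=pair_matrix(assignments),
        combos=combos,
    )


def _pct(value: float, digits: int = 0) -> str:
    """Percent string with half-up rounding (0 digits -> '60%', 2 -> '5.37%')."""
    q = Decimal(1).scaleb(-digits)
    return f"{Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)}%"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tables(result: PipelineResult, path: Path) -> None:
    codes = result.vocab.codes
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in result.reports:
            m = r.motif
            fh.write(f"AC\t{m.accession}\n")
            fh.write(f"NAME\t{m.name}\n")
            fh.write(f"TYPE\t{m.kind}\n")
            fh.write(f"DE\t{m.description}\n")
            if m.consensus:
                fh.write(f"CONSENSUS\t{m.consensus}\n")
            fh.write("LOC\t" + "\t".join(codes) + "\n")
            for label, counts, enr in (
                ("TP", r.tp_counts, r.tp_enrichment),
                ("FP", r.fp_counts, r.fp_enrichment),
            ):
                cells = []
                for c in codes:
                    val = str(counts.L.get(c, 0))
                    if enr is not None and c in enr.enriched_codes:
                        val += "*"
                    cells.append(val)
                fh.write(f"{label}\t" + "\t".join(cells) + "\n")
            fh.write(f"CATEGORY\t{r.category.value}\n")
            if r.fisher is not None and r.fisher.p_value is not None:
                star = "\t*" if r.fisher.significant else ""
                fh.write(f"FISHER\t{r.fisher.p_value:.6g}\t{r.fisher.method}{star}\n")
            elif r.fisher is not None:
                fh.write(f"FISHER\tskipped: {r.fisher.skip}\n")
            fh.write("//\n")


def _statistics_dict(result: PipelineResult) -> dict:
    ds = result.dataset
    freq = dataset_frequencies(ds)
    coverage = result.coverage_by_kind()
    hist = result.assignment_histogram
    n_assignable = sum(hist.values())
    stats = {
        "dataset": {
            "mode": ds.mode,
            "N": ds.N,
            "K": dict(ds.K),
            "multi_count": ds.multi_count(),
            "multi_percent": 100.0 * ds.multi_count() / ds.N if ds.N else 0.0,
            "frequencies": {
                str(idx): {
                    "count": int(row["count"]),
                    "percent": float(row["percent"]),
                }
                for idx, row in freq.iterrows()
            },
        },
        "coverage": coverage,
        "categories": {cat.value: n for cat, n in result.category_counts.items()},
        "assignment_histogram": {str(k): v for k, v in sorted(hist.items())},
        "assignable_motifs": n_assignable,
        "fisher": {
            "tested": result.fisher_tested,
            "significant": result.fisher_significant,
            "significant_percent": (
                100.0 * result.fisher_significant / result.fisher_tested
                if result.fisher_tested
                else 0.0
            ),
        },
        "pair_matrix": {
            "singles": dict(sorted(result.pair.singles.items())),
            "pairs": {
                "+".join(sorted(pair)): n
                for pair, n in sorted(
                    result.pair.pairs.items(), key=lambda it: tuple(sorted(it[0]))
                )
            },
        },
        "combinations": {
            str(k): [
                {"compartments": sorted(combo), "R": r} for combo, r in table.rows
            ]
            for k, table in result.combos.items()
        },
    }
    return stats


def _write_statistics(result: PipelineResult, path: Path) -> None:
    ds = result.dataset
    stats = _statistics_dict(result)
    lines: list[str] = []
    lines.append(f"# Dataset ({ds.mode}): N={ds.N} localized proteins")
    lines.append("compartment\tcount\tpercent")
    for code, row in stats["dataset"]["frequencies"].items():
        lines.append(f"{code}\t{row['count']}\t{_pct(row['percent'], 1)}")
    lines.append("")
    lines.append("# Coverage by motif kind (localized / total set members)")
    lines.append("kind\tmotifs\tTP\tFP")
    for kind in ("matrix", "pattern", "total"):
        cov = stats["coverage"][kind]
        tp_pct = 100.0 * cov["tp_localized"] / cov["tp_total"] if cov["tp_total"] else 0.0
        fp_pct = 100.0 * cov["fp_localized"] / cov["fp_total"] if cov["fp_total"] else 0.0
        lines.append(
            f"{kind}\t{cov['motifs']}\t{cov['tp_localized']} ({_pct(tp_pct)})"
            f"\t{cov['fp_localized']} ({_pct(fp_pct)})"
        )
    lines.append("")
    lines.append("# Motif categories")
    for cat, n in stats["categories"].items():
        lines.append(f"{cat}\t{n}")
    lines.append("")
    lines.append("# Assigned compartments per motif")
    lines.append("n_compartments\tmotifs\tpercent")
    total_assignable = stats["assignable_motifs"]
    for k, v in stats["assignment_histogram"].items():
        pct = 100.0 * v / total_assignable if total_assignable else 0.0
        lines.append(f"{k}\t{v}\t{_pct(pct, 2)}")
    lines.append("")
    f = stats["fisher"]
    lines.append("# TP-vs-FP heterogeneity (Fisher 2xc)")
    lines.append(
        f"tested\t{f['tested']}\nsignificant\t{f['significant']}"
        f"\t{_pct(f['significant_percent'])}"
    )
    lines.append("")
    lines.append("# Pair matrix (diagonal = single-compartment motifs)")
    df = result.pair.to_dataframe(result.vocab)
    lines.append("\t" + "\t".join(df.columns))
    for idx, row in df.iterrows():
        lines.append(str(idx) + "\t" + "\t".join(str(v) for v in row))
    lines.append("2SL\t" + "\t".join(str(result.pair.two_sl(c)) for c in df.columns))
    lines.append(
        "1SL-2SL\t"
        + "\t".join(str(result.pair.one_sl_minus_two_sl(c)) for c in df.columns)
    )
    for k, table in result.combos.items():
        lines.append("")
        lines.append(f"# Combinations of {k} compartments")
        lines.append("compartments\tR")
        for combo, r in table.rows:
            lines.append(",".join(sorted(combo)) + f"\t{r}")
        lines.append("N\t" + "\t".join(f"{c}={table.n_of(c)}" for c in result.vocab.codes))
        lines.append(
            "NxR\t" + "\t".join(f"{c}={table.nxr_of(c)}" for c in result.vocab.codes)
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def run_pipeline(
    swissprot_path: str | Path,
    prosite_path: str | Path,
    out_prefix: str | Path,
    motif_kind_filter: str = "all",
    compartment_mode: str = "twelve",
    dataset_mode: str = "multiple",
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
    vocab: CompartmentVocabulary | None = None,
    progress: bool = False,
) -> PipelineResult:
    """Run the full analysis and write the report files.

    ``motif_kind_filter`` is ``pattern``, ``matrix`` or ``all``;
    ``compartment_mode`` is ``twelve`` or ``seven`` (ignored when an explicit
    ``vocab`` is given); ``dataset_mode`` is ``multiple`` or ``single_only``.
    """
    if motif_kind_filter not in ("pattern", "matrix", "all"):
        raise ValueError("motif_kind_filter must be 'pattern', 'matrix' or 'all'")
    if dataset_mode not in ("multiple", "single_only"):
        raise ValueError("dataset_mode must be 'multiple' or 'single_only'")
    swissprot_path = Path(swissprot_path)
    prosite_path = Path(prosite_path)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if vocab is None:
        vocab = CompartmentVocabulary.default(compartment_mode)

    logger.info("parsing %s", swissprot_path)
    records = parse_swissprot(swissprot_path)
    ds = build_dataset(records, vocab)
    if dataset_mode == "single_only":
        ds = restrict_single(ds)
    logger.info("dataset: N=%d localized proteins (%s)", ds.N, ds.mode)

    logger.info("parsing %s", prosite_path)
    alias = build_alias_index(records)
    motifs = parse_prosite(prosite_path, alias_index=alias)
    if motif_kind_filter != "all":
        motifs = [m for m in motifs if m.kind == motif_kind_filter]
    if not motifs:
        raise ValueError(
            f"no motifs left after kind filter {motif_kind_filter!r}; nothing to do"
        )
    logger.info("analyzing %d motifs", len(motifs))
    result = analyze_motifs(motifs, ds, alpha=alpha, correction=correction,
                            progress=progress)

    write_mapping(ds, Path(f"{out_prefix}.mapping"))
    _write_tables(result, Path(f"{out_prefix}.tables"))
    _write_statistics(result, Path(f"{out_prefix}.statistics"))
    with open(f"{out_prefix}.statistics.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_statistics_dict(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {
            "swissprot": {"path": str(swissprot_path), "sha256": _sha256(swissprot_path)},
            "prosite": {"path": str(prosite_path), "sha256": _sha256(prosite_path)},
        },
        "parameters": {
            "motif_kind_filter": motif_kind_filter,
            "compartment_mode": vocab.mode,
            "dataset_mode": dataset_mode,
            "alpha": alpha,
            "correction": correction,
        },
    }
    with open(f"{out_prefix}.manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
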