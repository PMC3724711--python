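"""Exact Fisher test for 2xc tables: TP-vs-FP localization heterogeneity.

For each motif the localized TP and FP proteins are tallied into a 2-row
contingency table over the compartments occurring in either set (a
multi-compartment protein increments several columns).  The Freeman-Halton
extension of Fisher's exact test then sums, over all tables with the
observed row and column margins, the conditional (multivariate
hypergeometric) probabilities of tables no more probable than the observed
one.  Tables whose probability ties the observed one within a relative
tolerance are included in the tail (the conservative convention).

Enumeration is depth-first over the row-1 column counts with margin
feasibility pruning; when the candidate-table bound exceeds the enumeration
budget, a Monte Carlo estimate over the fixed-margin null replaces the
exact sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .enrichment import MotifCategory, classify_motif, count_set
from .prosite_io import MotifRecord
from .sprot_io import LocalizationDataset

__all__ = [
    "ContingencyTable2xc",
    "SkipReason",
    "EnumerationBudgetError",
    "build_table",
    "fisher_2xc_exact",
    "fisher_2xc_mc",
    "FisherOutcome",
    "test_motif",
]

#: Relative tolerance within which a candidate table's probability is
#: considered tied with the observed one (ties are included in the tail).
TIE_REL_TOL = 1e-7

#: Default cap on the number of candidate tables the exact engine may visit.
DEFAULT_BUDGET = 50_000_000

#: Defaults for the Monte Carlo fallback.
DEFAULT_MC_REPS = 1_000_000
DEFAULT_MC_SEED = 20120711


class EnumerationBudgetError(RuntimeError):
    """Exact enumeration would exceed the budget; use fisher_2xc_mc."""


@dataclass(frozen=True)
class SkipReason:
    """A motif excluded from Fisher testing, with the reason why."""

    reason: str


@dataclass(frozen=True)
class ContingencyTable2xc:
    """2 x c table of localized TP (row 1) and FP (row 2) compartment counts.

    Columns where both rows are zero are dropped at construction.
    """

    columns: tuple[str, ...]
    row_tp: tuple[int, ...]
    row_fp: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.columns) == len(self.row_tp) == len(self.row_fp)):
            raise ValueError("columns and rows must have equal length")
        if any(a < 0 or b < 0 for a, b in zip(self.row_tp, self.row_fp)):
            raise ValueError("counts must be non-negative")
        keep = [i for i in range(len(self.columns)) if self.row_tp[i] or self.row_fp[i]]
        if not keep:
            raise ValueError("table has no non-empty column")
        if len(keep) != len(self.columns):
            object.__setattr__(self, "columns", tuple(self.columns[i] for i in keep))
            object.__setattr__(self, "row_tp", tuple(self.row_tp[i] for i in keep))
            object.__setattr__(self, "row_fp", tuple(self.row_fp[i] for i in keep))

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(a + b for a, b in zip(self.row_tp, self.row_fp))

    @property
    def row_totals(self) -> tuple[int, int]:
        return sum(self.row_tp), sum(self.row_fp)

    @property
    def total(self) -> int:
        return sum(self.col_totals)


def build_table(
    motif: MotifRecord, ds: LocalizationDataset
) -> ContingencyTable2xc | SkipReason:
    """Build the TP/FP localization table for one motif, or a skip reason.

    Motifs are skipped when either set has fewer than two localized proteins
    (too little data for a heterogeneity test) or when TP and FP occupy one
    and the same single compartment (degenerate 2x1 table).
    """
    tp = count_set(motif.tp_accessions, ds)
    fp = count_set(motif.fp_accessions, ds)
    if tp.n < 2 or fp.n < 2:
        return SkipReason("single-sequence set")
    codes = [c for c in ds.vocab.codes if tp.L.get(c, 0) or fp.L.get(c, 0)]
    if len(codes) < 2:
        return SkipReason("single shared compartment")
    return ContingencyTable2xc(
        columns=tuple(codes),
        row_tp=tuple(tp.L[c] for c in codes),
        row_fp=tuple(fp.L[c] for c in codes),
    )


def _log_table_prob(cols: Sequence[int], row1: Sequence[int], n: int, r1: int) -> float:
    """Log conditional probability of a table given fixed margins.

    P = prod_j C(c_j, a_j) / C(n, r1), where a_j is the row-1 count.
    """
    c = np.asarray(cols, dtype=float)
    a = np.asarray(row1, dtype=float)
    log_num = float(np.sum(gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)))
    log_den = float(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    return log_num - log_den


def _enumeration_bound(cols: Sequence[int], r1: int) -> float:
    bound = 1.0
    for c in cols:
        bound *= min(c, r1) + 1
    return bound


def fisher_2xc_exact(
    table: ContingencyTable2xc, budget: int = DEFAULT_BUDGET
) -> float:
    """Freeman-Halton exact p-value for a 2xc table.

    Raises :class:`EnumerationBudgetError` when the number of candidate
    tables would exceed ``budget``; callers should then fall back to
    :func:`fisher_2xc_mc`.
    """
    cols = table.col_totals
    r1, r2 = table.row_totals
    n = table.total
    if n < 1:
        raise ValueError("table must have at least one observation")
    if r1 == 0 or r2 == 0 or len(cols) == 1:
        return 1.0  # only one table has these margins
    if _enumeration_bound(cols, r1) > budget:
        raise EnumerationBudgetError(
            f"candidate-table bound exceeds budget {budget}; use fisher_2xc_mc"
        )
    log_obs = _log_table_prob(cols, table.row_tp, n, r1)
    threshold = log_obs + math.log1p(TIE_REL_TOL)

    # Precompute log C(c_j, a) for every column and feasible a.
    log_choose = [
        [
            float(gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1))
            for a in range(c + 1)
        ]
        for c in cols
    ]
    log_den = float(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    # suffix sums of column totals, for margin-feasibility pruning
    suffix = [0] * (len(cols) + 1)
    for i in range(len(cols) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + cols[i]

    tail = 0.0
    visited = 0
    stack = [(0, r1, 0.0)]  # (column index, remaining row-1 margin, partial log prob)
    while stack:
        j, rem, logp = stack.pop()
        if j == len(cols):
            visited += 1
            if visited > budget:
                raise EnumerationBudgetError(
                    f"exceeded enumeration budget {budget}; use fisher_2xc_mc"
                )
            if logp - log_den <= threshold:
                tail += math.exp(logp - log_den)
            continue
        lo = max(0, rem - suffix[j + 1])
        hi = min(cols[j], rem)
        for a in range(lo, hi + 1):
            stack.append((j + 1, rem - a, logp + log_choose[j][a]))
    return float(min(1.0, tail))


def fisher_2xc_mc(
    table: ContingencyTable2xc,
    reps: int = 100_000,
    seed: int = DEFAULT_MC_SEED,
) -> tuple[float, float]:
    """Monte Carlo Freeman-Halton p-value with its binomial standard error.

    Row-1 column counts are sampled from the multivariate hypergeometric
    distribution with the observed margins; the estimate is the fraction of
    sampled tables no more probable than the observed one.  Deterministic
    for a fixed seed.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a usable estimate")
    cols = np.asarray(table.col_totals)
    r1, r2 = table.row_totals
    n = table.total
    if r1 == 0 or r2 == 0 or len(cols) == 1:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, r1, size=reps).astype(float)
    cols_f = cols.astype(float)
    logp = np.sum(
        gammaln(cols_f + 1) - gammaln(draws + 1) - gammaln(cols_f - draws + 1), axis=1
    )
    log_obs = float(
        np.sum(
            gammaln(cols_f + 1)
            - gammaln(np.asarray(table.row_tp, dtype=float) + 1)
            - gammaln(cols_f - np.asarray(table.row_tp, dtype=float) + 1)
        )
    )
    hits = int(np.sum(logp <= log_obs + math.log1p(TIE_REL_TOL)))
    p_hat = hits / reps
    se = math.sqrt(p_hat * (1.0 - p_hat) / reps)
    return p_hat, se


@dataclass(frozen=True)
class FisherOutcome:
    """Result of the TP-vs-FP heterogeneity test for one motif."""

    p_value: float | None
    significant: bool
    method: str | None  # "exact" | "mc" | None when skipped
    skip: str | None = None
    se: float | None = None


def test_motif(
    motif: MotifRecord,
    ds: LocalizationDataset,
    alpha: float = 0.05,
    budget: int = DEFAULT_BUDGET,
    mc_reps: int = DEFAULT_MC_REPS,
    mc_seed: int = DEFAULT_MC_SEED,
) -> FisherOutcome:
    """Run the heterogeneity test for one (testable) motif.

    Builds the TP/FP table, prefers the exact engine and falls back to the
    Monte Carlo engine when the table is too large to enumerate.
    """
    if classify_motif(motif, ds) is not MotifCategory.TESTABLE:
        return FisherOutcome(None, False, None, skip="motif not testable")
    table = build_table(motif, ds)
    if isinstance(table, SkipReason):
        return FisherOutcome(None, False, None, skip=table.reason)
    try:
        p = fisher_2xc_exact(table, budget=budget)
        return FisherOutcome(p, p <= alpha, "exact")
    except EnumerationBudgetError:
        p, se = fisher_2xc_mc(table, reps=mc_reps, seed=mc_seed)
        return FisherOutcome(p, p <= alpha, "mc", se=se)
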