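"""Hypergeometric compartment enrichment of motif TP/FP sets.

The database holds ``N`` localization-annotated proteins, ``K`` of which
carry compartment ``X``.  A motif's TP (or FP) set contains ``n`` annotated
proteins, ``L`` of which carry ``X``.  Under the null hypothesis that the
set is a uniform draw from the database, the number carrying ``X`` is
hypergeometric, and the upper-tail probability

    p = sum_{k = L}^{min(K, n)}  C(K, k) C(N-K, n-k) / C(N, n)

measures enrichment.  A compartment is assigned to the set when p <= alpha
(0.05 by default) AND its frequency in the set strictly exceeds the database
frequency (L/n > K/N).  Probabilities are computed in log-space with
log-gamma factorials, so arbitrarily large databases are safe.

No multiple-testing correction is applied by default (raw p-values against
alpha); Bonferroni or Benjamini-Hochberg across the compartments of one set
can be requested explicitly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln

from .prosite_io import MotifRecord
from .sprot_io import LocalizationDataset

__all__ = [
    "hypergeom_pmf",
    "hypergeom_pvalue",
    "SetLocalizationCounts",
    "count_set",
    "CompartmentEnrichment",
    "EnrichmentResult",
    "enrich_set",
    "MotifCategory",
    "classify_motif",
    "assign_motif_localizations",
]

DEFAULT_ALPHA = 0.05


def _check_universe(N: int, K: int, n: int) -> None:
    if N < 0 or K < 0 or n < 0:
        raise ValueError(f"N, K, n must be non-negative (got N={N}, K={K}, n={n})")
    if K > N or n > N:
        raise ValueError(f"K and n cannot exceed N (got N={N}, K={K}, n={n})")


def _log_binom(n: float | np.ndarray, k: float | np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_pmf_support(N: int, K: int, n: int) -> tuple[int, int, np.ndarray]:
    """Log-pmf over the support [max(0, n-(N-K)), min(K, n)]."""
    k_min = max(0, n - (N - K))
    k_max = min(K, n)
    k = np.arange(k_min, k_max + 1)
    logp = _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)
    return k_min, k_max, logp


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for a hypergeometric draw of n from N with K successes."""
    _check_universe(N, K, n)
    k_min = max(0, n - (N - K))
    k_max = min(K, n)
    if k < k_min or k > k_max:
        return 0.0
    logp = _lchoose(K, k) + _lchoose(N - K, n - k) - _lchoose(N, n)
    return float(min(1.0, math.exp(logp)))


def hypergeom_pvalue(N: int, K: int, n: int, L: int) -> float:
    """Upper-tail P(X >= L); equals 1 whenever L is at or below the support
    minimum, and 0 when L exceeds min(K, n) (empty sum).

    The leading term P(X = L) is computed in log-space; the rest of the tail
    follows from the pmf's multiplicative recurrence
    P(k+1)/P(k) = (K-k)(n-k) / ((k+1)(N-K-n+k+1)), whose terms are all <= 1
    relative to the leading term, so the sum is overflow- and
    underflow-safe at any database size.
    """
    _check_universe(N, K, n)
    if L < 0 or L > n:
        raise ValueError(f"L must be in [0, n] (got L={L}, n={n})")
    k_max = min(K, n)
    if L > k_max:
        return 0.0
    if L <= max(0, n - (N - K)):
        return 1.0
    log_lead = _lchoose(K, L) + _lchoose(N - K, n - L) - _lchoose(N, n)
    ratio = 1.0
    total = 1.0
    for k in range(L, k_max):
        ratio *= (K - k) * (n - k) / ((k + 1.0) * (N - K - n + k + 1.0))
        total += ratio
    return float(min(1.0, math.exp(log_lead + math.log(total))))


@dataclass(frozen=True)
class SetLocalizationCounts:
    """Localization tally of one motif set (TP or FP).

    ``n`` counts only the proteins present in the dataset (i.e. with at
    least one assigned compartment); ``n_total`` is the full set size, so
    ``n / n_total`` is the set's localization coverage.
    """

    n: int
    L: Mapping[str, int]
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.n_total):
            raise ValueError("need 0 <= n <= n_total")
        for c, l in self.L.items():
            if not (0 <= l <= self.n):
                raise ValueError(f"L[{c}]={l} outside [0, n={self.n}]")


def count_set(accessions: Iterable[str], ds: LocalizationDataset) -> SetLocalizationCounts:
    """Tally compartments over the dataset members of an accession set.

    A multi-compartment protein counts once for each compartment it carries.
    """
    accessions = set(accessions)
    L = {c: 0 for c in ds.vocab.codes}
    n = 0
    for acc in accessions:
        codes = ds.assignments.get(acc)
        if codes is None:
            continue
        n += 1
        for c in codes:
            L[c] += 1
    return SetLocalizationCounts(n=n, L=L, n_total=len(accessions))


@dataclass(frozen=True)
class CompartmentEnrichment:
    code: str
    L: int
    p_value: float
    enriched: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-compartment enrichment of one set against the database background."""

    records: tuple[CompartmentEnrichment, ...]
    n: int
    N: int
    K: Mapping[str, int]

    @property
    def enriched_codes(self) -> frozenset[str]:
        return frozenset(r.code for r in self.records if r.enriched)

    def p_value(self, code: str) -> float:
        for r in self.records:
            if r.code == code:
                return r.p_value
        raise KeyError(code)


def enrich_set(
    counts: SetLocalizationCounts,
    ds: LocalizationDataset,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
) -> EnrichmentResult:
    """Test every compartment for over-representation in one set.

    A compartment with ``L = 0`` gets p = 1 and is never enriched.  The
    enrichment flag requires both p <= alpha and a set frequency strictly
    above the database frequency.  ``correction`` may be ``"bonferroni"`` or
    ``"bh"`` to adjust the p-values across the compartments of this set
    (off by default: raw p-values against alpha).
    """
    if counts.n < 1:
        raise ValueError("enrich_set needs at least one localized protein; "
                         "classify the motif instead")
    N = ds.N
    n = counts.n
    pvals = []
    for c in ds.vocab.codes:
        L = counts.L.get(c, 0)
        pvals.append(1.0 if L == 0 else hypergeom_pvalue(N, ds.K[c], n, L))
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(correction)
        if method is None:
            raise ValueError(f"correction must be 'bonferroni' or 'bh', got {correction!r}")
        pvals = list(multipletests(pvals, method=method)[1])
    records = []
    for c, p in zip(ds.vocab.codes, pvals):
        L = counts.L.get(c, 0)
        enriched = L > 0 and p <= alpha and L * N > ds.K[c] * n  # L/n > K/N, exact
        records.append(CompartmentEnrichment(code=c, L=L, p_value=float(p), enriched=enriched))
    return EnrichmentResult(records=tuple(records), n=n, N=N, K=dict(ds.K))


class MotifCategory(enum.Enum):
    """Mutually exclusive and exhaustive motif classes by localization data.

    ``TESTABLE`` motifs have localization data on both sides and more than a
    single shared compartment, so TP-vs-FP heterogeneity can be tested.
    """

    EMPTY_MOTIF = "empty_motif"
    EMPTY_TP = "empty_tp"
    EMPTY_FP = "empty_fp"
    TP_EQ_FP = "tp_eq_fp"
    TESTABLE = "testable"


def classify_motif(motif: MotifRecord, ds: LocalizationDataset) -> MotifCategory:
    """Classify a motif by the localization data available on each side."""
    tp = count_set(motif.tp_accessions, ds)
    fp = count_set(motif.fp_accessions, ds)
    if tp.n == 0 and fp.n == 0:
        return MotifCategory.EMPTY_MOTIF
    if tp.n == 0:
        return MotifCategory.EMPTY_TP
    if fp.n == 0:
        return MotifCategory.EMPTY_FP
    tp_codes = {c for c, l in tp.L.items() if l}
    fp_codes = {c for c, l in fp.L.items() if l}
    if len(tp_codes) == 1 and tp_codes == fp_codes:
        return MotifCategory.TP_EQ_FP
    return MotifCategory.TESTABLE


def assign_motif_localizations(
    motif: MotifRecord, ds: LocalizationDataset, alpha: float = DEFAULT_ALPHA
) -> frozenset[str]:
    """A motif's compartments: those enriched in its TP set.

    Requires at least one localized TP protein; the result may be empty when
    no compartment passes the enrichment rule.
    """
    counts = count_set(motif.tp_accessions, ds)
    if counts.n == 0:
        raise ValueError(f"{motif.accession}: no localized TP protein to assign from")
    return enrich_set(counts, ds, alpha=alpha).enriched_codes
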