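"""Compartment co-occurrence summaries across motif assignments.

Motifs assigned exactly one compartment populate the diagonal of the pair
matrix; motifs assigned exactly two populate its off-diagonal cells
(unordered pairs, so the matrix is symmetric).  Combination tables list the
distinct compartment sets of size k (k >= 3) with the number of motifs
carrying each.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .compartments import CompartmentVocabulary

__all__ = ["PairMatrix", "ComboTable", "pair_matrix", "combo_table",
           "assignment_size_histogram"]


@dataclass(frozen=True)
class PairMatrix:
    """Single- and dual-compartment motif counts.

    ``singles[c]`` counts motifs assigned exactly compartment ``c``;
    ``pairs[{a, b}]`` counts motifs assigned exactly the pair.  ``2SL`` is a
    compartment's total over all pairs containing it, and ``1SL - 2SL``
    contrasts lone against paired usage.
    """

    singles: Mapping[str, int]
    pairs: Mapping[frozenset[str], int]

    def two_sl(self, code: str) -> int:
        return sum(r for pair, r in self.pairs.items() if code in pair)

    def one_sl_minus_two_sl(self, code: str) -> int:
        return self.singles.get(code, 0) - self.two_sl(code)

    def to_dataframe(self, vocab: CompartmentVocabulary) -> pd.DataFrame:
        """Symmetric code x code matrix; diagonal = single-assignment counts."""
        codes = list(vocab.codes)
        df = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
        for c, r in self.singles.items():
            df.loc[c, c] = r
        for pair, r in self.pairs.items():
            a, b = sorted(pair)
            df.loc[a, b] = r
            df.loc[b, a] = r
        return df


@dataclass(frozen=True)
class ComboTable:
    """Motif counts per distinct compartment combination of size k.

    ``rows`` is sorted by count descending, then lexicographically.  Per
    compartment, ``N`` is the number of distinct combinations containing it
    and ``NxR`` the total motif count over those combinations.
    """

    k: int
    rows: tuple[tuple[frozenset[str], int], ...]

    def n_of(self, code: str) -> int:
        return sum(1 for combo, _ in self.rows if code in combo)

    def nxr_of(self, code: str) -> int:
        return sum(r for combo, r in self.rows if code in combo)

    def to_dataframe(self, vocab: CompartmentVocabulary) -> pd.DataFrame:
        """0/1 incidence of each combination over the compartments, plus R."""
        codes = list(vocab.codes)
        data = []
        for combo, r in self.rows:
            row = {c: int(c in combo) for c in codes}
            row["R"] = r
            data.append(row)
        return pd.DataFrame(data, columns=codes + ["R"], dtype=int)


def pair_matrix(assignments: Mapping[str, frozenset[str]]) -> PairMatrix:
    """Tally single- and pair-assigned motifs (others are ignored here)."""
    singles: Counter[str] = Counter()
    pairs: Counter[frozenset[str]] = Counter()
    for codes in assignments.values():
        if len(codes) == 1:
            singles[next(iter(codes))] += 1
        elif len(codes) == 2:
            pairs[frozenset(codes)] += 1
    return PairMatrix(singles=dict(singles), pairs=dict(pairs))


def combo_table(assignments: Mapping[str, frozenset[str]], k: int) -> ComboTable:
    """Tally motifs assigned exactly k compartments, by distinct combination."""
    if k < 3:
        raise ValueError("combo_table is for k >= 3; use pair_matrix below that")
    combos: Counter[frozenset[str]] = Counter()
    for codes in assignments.values():
        if len(codes) == k:
            combos[frozenset(codes)] += 1
    rows = sorted(combos.items(), key=lambda item: (-item[1], tuple(sorted(item[0]))))
    return ComboTable(k=k, rows=tuple(rows))


def assignment_size_histogram(
    assignments: Mapping[str, frozenset[str]]
) -> dict[int, int]:
    """Histogram of assignment sizes (number of compartments per motif)."""
    hist: Counter[int] = Counter(len(codes) for codes in assignments.values())
    return dict(sorted(hist.items()))
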