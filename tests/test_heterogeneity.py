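import itertools
import math
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from motif_localize.heterogeneity import (ContingencyTable2xc,
                                          EnumerationBudgetError, SkipReason,
                                          build_table, fisher_2xc_exact,
                                          fisher_2xc_mc)
from motif_localize.heterogeneity import test_motif as run_motif_test

from conftest import make_dataset, make_motif


def oracle_freeman_halton(row1, row2):
    """Independent brute-force enumerator over all fixed-margin tables.

    Exact integer arithmetic: probabilities are integer numerators over the
    common denominator C(n, r1), so ties are exact and the total is checked
    to be exactly 1.
    """
    cols = [a + b for a, b in zip(row1, row2)]
    r1, n = sum(row1), sum(cols)
    if r1 == 0 or sum(row2) == 0 or len(cols) == 1:
        return 1.0
    den = comb(n, r1)
    obs = math.prod(comb(c, a) for c, a in zip(cols, row1))
    total = tail = 0
    for a in itertools.product(*[range(c + 1) for c in cols]):
        if sum(a) != r1:
            continue
        num = math.prod(comb(c, x) for c, x in zip(cols, a))
        total += num
        if num <= obs:
            tail += num
    assert total == den  # the conditional distribution sums to one
    return tail / den


def iter_tables(n_cols, max_total):
    for total in range(1, max_total + 1):
        for cells in itertools.product(range(total + 1), repeat=2 * n_cols):
            if sum(cells) != total:
                continue
            row1, row2 = cells[:n_cols], cells[n_cols:]
            if any(a + b == 0 for a, b in zip(row1, row2)):
                continue  # zero columns are dropped; same table appears smaller
            yield row1, row2


def as_table(row1, row2):
    return ContingencyTable2xc(
        columns=tuple(f"c{i}" for i in range(len(row1))), row_tp=row1, row_fp=row2
    )


def test_disjoint_three_by_three_table_has_p_point_one():
    assert fisher_2xc_exact(as_table((3, 0), (0, 3))) == pytest.approx(0.1, abs=1e-12)


def test_identical_rows_give_p_one():
    assert fisher_2xc_exact(as_table((5, 5), (5, 5))) == pytest.approx(1.0, abs=1e-12)


def test_two_by_three_example_matches_enumeration_oracle():
    # exhaustively enumerable by hand: margins (3,3) / (2,2,2)
    assert fisher_2xc_exact(as_table((2, 1, 0), (0, 1, 2))) == pytest.approx(
        0.6, abs=1e-12
    )


@pytest.mark.parametrize("n_cols", [2, 3])
def test_exact_engine_matches_brute_force_on_all_small_tables(n_cols):
    for row1, row2 in iter_tables(n_cols, 12):
        expected = oracle_freeman_halton(row1, row2)
        assert fisher_2xc_exact(as_table(row1, row2)) == pytest.approx(
            expected, abs=1e-10
        ), (row1, row2)


def test_two_by_two_tables_match_classical_two_sided_fisher():
    for row1, row2 in iter_tables(2, 12):
        if sum(row1) == 0 or sum(row2) == 0:
            continue
        ours = fisher_2xc_exact(as_table(row1, row2))
        reference = fisher_exact([list(row1), list(row2)], alternative="two-sided")[1]
        assert ours == pytest.approx(reference, abs=1e-9), (row1, row2)


def test_exact_p_is_invariant_under_column_permutation_and_row_swap():
    rng = np.random.default_rng(5)
    for _ in range(25):
        c = int(rng.integers(2, 5))
        row1 = tuple(int(x) for x in rng.integers(0, 6, size=c))
        row2 = tuple(int(x) for x in rng.integers(0, 6, size=c))
        if all(a + b == 0 for a, b in zip(row1, row2)):
            continue
        keep = [i for i in range(c) if row1[i] or row2[i]]
        row1 = tuple(row1[i] for i in keep)
        row2 = tuple(row2[i] for i in keep)
        p = fisher_2xc_exact(as_table(row1, row2))
        perm = list(rng.permutation(len(row1)))
        p_perm = fisher_2xc_exact(
            as_table(tuple(row1[i] for i in perm), tuple(row2[i] for i in perm))
        )
        p_swap = fisher_2xc_exact(as_table(row2, row1))
        assert p == pytest.approx(p_perm, rel=1e-12)
        assert p == pytest.approx(p_swap, rel=1e-12)


def test_budget_overflow_raises_and_mc_takes_over():
    wide = as_table(tuple([30] * 8), tuple([30] * 8))
    with pytest.raises(EnumerationBudgetError):
        fisher_2xc_exact(wide, budget=10_000)
    p, se = fisher_2xc_mc(wide, reps=2000, seed=1)
    assert p > 0.5  # identical rows: observed table is the mode


def test_mc_estimates_agree_with_exact_engine_within_three_se():
    rng = np.random.default_rng(17)
    checked = 0
    deviations = []
    while checked < 50:
        c = int(rng.integers(2, 5))
        row1 = tuple(int(x) for x in rng.integers(0, 5, size=c))
        row2 = tuple(int(x) for x in rng.integers(0, 5, size=c))
        keep = [i for i in range(c) if row1[i] or row2[i]]
        if len(keep) < 2 or sum(row1) == 0 or sum(row2) == 0:
            continue
        row1 = tuple(row1[i] for i in keep)
        row2 = tuple(row2[i] for i in keep)
        table = as_table(row1, row2)
        exact = fisher_2xc_exact(table)
        estimate, se = fisher_2xc_mc(table, reps=20_000, seed=100 + checked)
        se = max(se, 1e-12)
        deviations.append(abs(estimate - exact) / se)
        checked += 1
    deviations = np.asarray(deviations)
    assert float(np.mean(np.abs(deviations))) <= 3.0
    assert float(np.max(deviations)) <= 5.0  # no single gross outlier


def test_mc_estimate_of_the_disjoint_table_brackets_the_exact_value():
    p, se = fisher_2xc_mc(as_table((3, 0), (0, 3)), reps=50_000, seed=2)
    assert abs(p - 0.1) <= 3 * se
    p_same, _ = fisher_2xc_mc(as_table((5, 5), (5, 5)), reps=5_000, seed=3)
    assert p_same == pytest.approx(1.0, abs=1e-12)


def test_mc_is_deterministic_for_a_fixed_seed():
    table = as_table((4, 1, 2), (1, 3, 2))
    assert fisher_2xc_mc(table, reps=5000, seed=9) == fisher_2xc_mc(
        table, reps=5000, seed=9
    )
    with pytest.raises(ValueError, match="reps"):
        fisher_2xc_mc(table, reps=10, seed=9)


def test_build_table_counts_and_skip_rules(vocab):
    ds = make_dataset(
        {
            "T1": {"Nuc"}, "T2": {"Nuc"}, "T3": {"Nuc"}, "T4": {"Nuc"},
            "F1": {"Mem"}, "F2": {"Mem"}, "F3": {"Mem"},
            "S1": {"cyt"}, "S2": {"cyt"}, "S3": {"cyt"}, "S4": {"cyt"},
        },
        vocab,
    )
    table = build_table(make_motif(tp=["T1", "T2", "T3", "T4"], fp=["F1", "F2", "F3"]), ds)
    assert table.columns == ("Mem", "Nuc")
    assert dict(zip(table.columns, table.row_tp)) == {"Nuc": 4, "Mem": 0}
    assert dict(zip(table.columns, table.row_fp)) == {"Nuc": 0, "Mem": 3}
    # fewer than two localized sequences on one side
    skip = build_table(make_motif(tp=["T1"], fp=["F1", "F2"]), ds)
    assert isinstance(skip, SkipReason) and skip.reason == "single-sequence set"
    # both sides confined to one and the same compartment
    skip = build_table(make_motif(tp=["S1", "S2"], fp=["S3", "S4"]), ds)
    assert isinstance(skip, SkipReason) and skip.reason == "single shared compartment"


def test_multi_compartment_proteins_increment_several_columns(vocab):
    ds = make_dataset(
        {"T1": {"Nuc", "cyt"}, "T2": {"Nuc"}, "F1": {"Mem"}, "F2": {"cyt"}}, vocab
    )
    table = build_table(make_motif(tp=["T1", "T2"], fp=["F1", "F2"]), ds)
    assert dict(zip(table.columns, table.row_tp)) == {"cyt": 1, "Nuc": 2, "Mem": 0}


def test_test_motif_end_to_end_on_disjoint_sets(vocab):
    assignments = {f"N{i}": {"Nuc"} for i in range(6)}
    assignments.update({f"M{i}": {"Mem"} for i in range(6)})
    assignments.update({f"B{i}": {"cyt"} for i in range(50)})
    ds = make_dataset(assignments, vocab)
    motif = make_motif(tp=[f"N{i}" for i in range(6)], fp=[f"M{i}" for i in range(6)])
    outcome = run_motif_test(motif, ds)
    assert outcome.method == "exact"
    assert outcome.significant and outcome.p_value <= 0.05
    # non-testable motifs are skipped, not tested
    same = make_motif(tp=["N0", "N1"], fp=["N2", "N3"])
    outcome = run_motif_test(same, ds)
    assert outcome.p_value is None and outcome.skip is not None
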