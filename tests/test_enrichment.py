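from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import motif_localize as ml
from motif_localize.enrichment import (MotifCategory, count_set, enrich_set,
                                       hypergeom_pmf, hypergeom_pvalue)

from conftest import make_dataset, make_motif


def rational_pmf(N, K, n, k):
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def rational_pvalue(N, K, n, L):
    return sum(rational_pmf(N, K, n, k) for k in range(L, min(K, n) + 1))


@pytest.mark.parametrize(
    "N, K, n, k, expected",
    [
        (10, 10, 3, 3, 1.0),
        (10, 0, 3, 0, 1.0),
        (50, 5, 10, 3, 0.044176782646453585),  # C(5,3) C(45,7) / C(50,10)
        (50, 5, 10, 6, 0.0),  # outside the support
    ],
)
def test_pmf_reference_values(N, K, n, k, expected):
    assert hypergeom_pmf(N, K, n, k) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "N, K, n, L, expected",
    [
        (50, 5, 10, 0, 1.0),  # full-support sum
        (1000, 200, 10, 0, 1.0),
        (50, 5, 10, 3, 0.0482603031962091),  # sum of k = 3, 4, 5
        (50, 5, 10, 6, 0.0),  # empty sum: L > min(K, n)
        (10, 8, 5, 3, 1.0),  # L at the support minimum
    ],
)
def test_pvalue_reference_values(N, K, n, L, expected):
    assert hypergeom_pvalue(N, K, n, L) == pytest.approx(expected, abs=1e-12)


def test_domain_errors():
    with pytest.raises(ValueError):
        hypergeom_pmf(10, 11, 3, 2)
    with pytest.raises(ValueError):
        hypergeom_pmf(10, -1, 3, 2)
    with pytest.raises(ValueError):
        hypergeom_pvalue(10, 5, 3, 4)  # L > n


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.data())
def test_pvalue_is_non_increasing_in_l_and_matches_rational_oracle(data):
    N = data.draw(st.integers(1, 80))
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    previous = None
    for L in range(0, n + 1):
        p = hypergeom_pvalue(N, K, n, L)
        assert 0.0 <= p <= 1.0
        if previous is not None:
            assert p <= previous + 1e-12  # non-increasing up to float noise
        previous = p
        assert p == pytest.approx(float(rational_pvalue(N, K, n, L)), abs=1e-12)


def test_pvalue_agrees_with_scipy_survival_function():
    for N, K, n, L in [(100, 20, 15, 5), (5000, 400, 60, 12), (37, 11, 22, 9)]:
        assert hypergeom_pvalue(N, K, n, L) == pytest.approx(
            float(hypergeom.sf(L - 1, N, K, n)), rel=1e-10
        )


def test_count_set_counts_each_compartment_once_per_protein(vocab):
    ds = make_dataset(
        {
            "P1": {"Nuc"}, "P2": {"Nuc"}, "P3": {"Nuc"}, "P4": {"Nuc", "cyt"},
        },
        vocab,
    )
    counts = count_set({"P1", "P2", "P3", "P4", "P9"}, ds)
    assert counts.n == 4
    assert counts.n_total == 5
    assert counts.L["Nuc"] == 4
    assert counts.L["cyt"] == 1
    empty = count_set(set(), ds)
    assert empty.n == 0 and all(v == 0 for v in empty.L.values())


def test_enrichment_requires_both_significance_and_excess_frequency(vocab):
    # background: 20% nuclear in a universe of 1000
    assignments = {f"B{i}": {"Nuc"} for i in range(200)}
    assignments.update({f"C{i}": {"cyt"} for i in range(800)})
    ds = make_dataset(assignments, vocab)
    counts = count_set({f"B{i}" for i in range(10)}, ds)  # all 10 nuclear
    result = enrich_set(counts, ds)
    nuc = next(r for r in result.records if r.code == "Nuc")
    assert nuc.enriched and nuc.p_value <= 0.05
    assert nuc.p_value == pytest.approx(
        float(rational_pvalue(1000, 200, 10, 10)), abs=1e-12
    )
    # compartments with L = 0 get p = 1 and are never enriched
    mem = next(r for r in result.records if r.code == "Mem")
    assert mem.p_value == 1.0 and not mem.enriched


def test_frequency_tie_is_not_enriched_even_when_p_small(vocab):
    # set frequency exactly equals background frequency: strict rule fails
    assignments = {f"A{i}": {"Nuc"} for i in range(50)}
    assignments.update({f"B{i}": {"cyt"} for i in range(50)})
    ds = make_dataset(assignments, vocab)
    counts = count_set({f"A{i}" for i in range(5)} | {f"B{i}" for i in range(5)}, ds)
    result = enrich_set(counts, ds, alpha=1.0)  # force the p criterion to pass
    nuc = next(r for r in result.records if r.code == "Nuc")
    assert counts.L["Nuc"] * ds.N == ds.K["Nuc"] * counts.n
    assert not nuc.enriched


def test_enrich_set_rejects_empty_sets(vocab):
    ds = make_dataset({"P1": {"Nuc"}}, vocab)
    with pytest.raises(ValueError, match="classify"):
        enrich_set(count_set(set(), ds), ds)


@pytest.mark.parametrize(
    "tp_loc, fp_loc, expected",
    [
        ([], [], MotifCategory.EMPTY_MOTIF),
        ([], [{"Nuc"}], MotifCategory.EMPTY_TP),
        ([{"Nuc"}], [], MotifCategory.EMPTY_FP),
        ([{"Nuc"}, {"Nuc"}], [{"Nuc"}], MotifCategory.TP_EQ_FP),
        ([{"Nuc"}], [{"Mem"}], MotifCategory.TESTABLE),
        ([{"Nuc", "cyt"}], [{"Nuc"}], MotifCategory.TESTABLE),
    ],
)
def test_motif_category_rules(vocab, tp_loc, fp_loc, expected):
    assignments = {}
    tp, fp = [], []
    for i, codes in enumerate(tp_loc):
        assignments[f"T{i}"] = codes
        tp.append(f"T{i}")
    tp.append("T_unlocalized")
    for i, codes in enumerate(fp_loc):
        assignments[f"F{i}"] = codes
        fp.append(f"F{i}")
    fp.append("F_unlocalized")
    ds = make_dataset(assignments or {"X": {"cyt"}}, vocab)
    motif = make_motif(tp=tp, fp=fp)
    assert ml.classify_motif(motif, ds) == expected


def test_categories_partition_every_cohort(demo_motifs, demo_dataset):
    counts = {cat: 0 for cat in MotifCategory}
    for motif in demo_motifs:
        counts[ml.classify_motif(motif, demo_dataset)] += 1
    assert sum(counts.values()) == len(demo_motifs)


def test_assignment_uses_only_the_tp_side(vocab):
    assignments = {f"N{i}": {"Nuc"} for i in range(100)}
    assignments.update({f"C{i}": {"cyt"} for i in range(900)})
    ds = make_dataset(assignments, vocab)
    motif = make_motif(tp=[f"N{i}" for i in range(10)], fp=[f"C{i}" for i in range(10)])
    assert ml.assign_motif_localizations(motif, ds) == {"Nuc"}
    with pytest.raises(ValueError, match="no localized TP"):
        ml.assign_motif_localizations(make_motif(tp=["absent"]), ds)


def test_planted_compartments_are_recovered_from_strong_motifs(
    demo_data, demo_motifs, demo_dataset
):
    strong = [
        m
        for m in demo_motifs
        if demo_data.truth.motifs[m.accession].spec.tp_rho >= 25
        and demo_data.truth.motifs[m.accession].spec.tp_size >= 30
        and len(demo_data.truth.motifs[m.accession].spec.tp_targets) == 1
    ]
    assert strong, "demo cohort should contain strong single-target motifs"
    for m in strong:
        targets = set(demo_data.truth.motifs[m.accession].spec.tp_targets)
        assert targets <= ml.assign_motif_localizations(m, demo_dataset)
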