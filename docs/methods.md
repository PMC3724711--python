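# Methods

## Localization model

Protein localization is taken from curated Swiss-Prot keywords only. Each
of twelve compartment-specific keywords maps to one three-letter code
(`Cytoplasm→cyt`, `Chloroplast→chl`, `Secreted→ext`, `Cell membrane→Mem`,
`Mitochondrion→Mit`, `Nucleus→Nuc`, `Periplasm→Per`,
`Endoplasmic reticulum→Ret`, `Golgi apparatus→Gol`, `Peroxisome→Prx`,
`Lysosome→Lys`, `Vacuole→Vac`); a protein receives the union of the codes
of its keywords. Matching is exact on whole keywords: the generic
`Membrane` keyword is deliberately *not* mapped, because it marks any
membrane association (organelle membranes included) and would contaminate
the plasma-membrane class. Free-text `CC SUBCELLULAR LOCATION` annotation
is not parsed; keywords are curated to a controlled vocabulary and make the
assignment reproducible across releases.

Two datasets are derived from one database: the *multiple* dataset keeps
every protein with at least one compartment, and the *single-only* dataset
keeps exactly the proteins with one compartment. The latter guards the
analysis against artifacts of multi-compartmental proteins (a `cyt`+`Nuc`
protein supports both columns of a contingency table at once).

The enrichment universe `N` is the number of localization-annotated
proteins, not the whole database. Proteins without a mapped keyword carry
no information for or against any compartment; including them would deflate
every background frequency `K/N` by a constant factor and inflate
enrichment calls for all compartments equally. Coverage (the fraction of a
motif's sequences that are annotated at all) is reported separately.

A reduced seven-compartment mode exists for coarse analyses. No canonical
seven-compartment subset is defined here; the default keeps the seven most
populated compartments (`cyt, chl, ext, Mem, Mit, Nuc, Per`, the first
seven of the vocabulary order) and the subset is configurable, as is the
whole keyword map via a two-column table.

## Enrichment test

For a motif set (TP or FP) with `n` localized members, `L` of them in
compartment `X` with background counts `K` of `N`, the upper tail
`P(X >= L)` of the hypergeometric distribution is computed with a
log-gamma leading term plus the pmf's multiplicative recurrence
`P(k+1)/P(k) = (K-k)(n-k) / ((k+1)(N-K-n+k+1))`. All downstream terms are
at most the leading term, so the sum neither overflows nor underflows at
any database size; against an exact-rational oracle the implementation is
accurate to ~1e-13 over an exhaustive grid `N <= 60`. Out-of-support `L`
returns 0 (empty sum) or 1 (full support) by convention.

A compartment is flagged for a set when `p <= alpha` (default 0.05) **and**
its set frequency strictly exceeds the background (`L·N > K·n`, computed in
integers to avoid float ties). The strict-excess condition matters at small
`n`, where a compartment can reach nominal significance while merely
matching the background. A motif's assigned compartments are the flagged
compartments of its **TP** set; FP enrichment is reported but never feeds
the assignment, since FP sequences by definition do not share the motif's
function. No multiple-testing correction is applied by default — each
compartment is reported at its raw p-value — but Bonferroni or
Benjamini–Hochberg across the twelve compartments of one set can be
switched on (`correction="bonferroni" | "bh"`).

Motifs are classified into five exhaustive categories before testing:
`empty_motif` (no localized protein on either side), `empty_tp`,
`empty_fp`, `tp_eq_fp` (both sides confined to one and the same
compartment) and `testable`.

## Heterogeneity test

The localized TP and FP proteins of a testable motif form a `2 x c` table
over the occupied compartments; a multi-compartment protein increments
every compartment it carries. Motifs with fewer than two localized
sequences on either side are skipped ("single-sequence set"): the discard
rule is interpreted in terms of *localized* sequences, the only reading
that affects the statistic — an unannotated sequence contributes nothing to
any cell. Tables with a single surviving column are skipped as degenerate
("single shared compartment").

The Freeman–Halton p-value sums the conditional probabilities (multivariate
hypergeometric, both margins fixed) of every table no more probable than
the observed one. Enumeration is depth-first over the row-1 column counts
with margin-feasibility pruning; probabilities come from a precomputed
log-binomial table per column. Ties are included in the tail when a
candidate's probability is within relative 1e-7 of the observed one — the
conservative convention, which also absorbs float noise in exact ties
(verified to 1e-10 against an integer-arithmetic enumerator on all 2x2 and
2x3 tables with total ≤ 12, and to the classical two-sided Fisher test on
2x2 margins).

When the candidate-table bound `Π_j (min(c_j, r_1)+1)` exceeds the
enumeration budget (default 5·10⁷), the exact sum is replaced by a Monte
Carlo estimate: row-1 vectors are sampled from the multivariate
hypergeometric null (10⁶ draws, fixed seed 20120711 for reproducibility)
and the estimate is the fraction of draws no more probable than the
observed table, with its binomial standard error. No asymptotic chi-square
fallback is offered; the test stays exact or simulation-consistent.

## Synthetic data generator

The generator emulates the joint structure the pipeline consumes: a protein
database with per-compartment background frequencies (defaults: large
compartments `cyt` 22%, `Mem` 12%, `Nuc` 12%, `ext` 10%; organelles 1–6%;
~30% of proteins unlocalized, so coverage denominators are exercised), a
multi-localization fraction (default 0.068, the rate observed for
keyword-annotated Swiss-Prot proteins), decor keywords including the
bookkeeping terms excluded by the keyword analysis, and a small fraction of
entries with secondary accessions that the motif records cite half the
time (exercising alias resolution). Motif TP/FP sets are drawn without
replacement with odds multiplier `rho` towards target compartments;
`rho = 1` is the exact uniform null. Ground truth (every protein's
compartments, every motif's membership and targets) is kept in a ledger,
and a fixed seed yields byte-identical files.

What the generator does **not** emulate: sequences (no SQ blocks, dummy
consensus patterns — irrelevant to a keyword-based analysis), correlated
compartment pairs (second compartments are drawn independently from the
background, so no mitochondrion/chloroplast-style linkage is planted),
incomplete or biased annotation (unlocalized proteins are missing at
random, while real annotation gaps correlate with organism and study
bias), and the heavy-tailed motif-size distribution of a real motif
database. Passing tests therefore demonstrate correctness of the counting
and the statistics under known truth, and calibration/power under clean
sampling — not robustness to annotation bias in real databases.

## Problem sizes and numerical choices

The test suite and the acceptance script run on desk-scale cohorts chosen
to make the statistical checks sharp while keeping the whole suite in the
tens of seconds: 500 null motifs (type-I error measured over 6 000
compartment tests and 500 Fisher tests), 200 planted replicates for
recovery (`rho = 50`, TP size 50, target background 10%) and for Fisher
power (disjoint TP/FP targets, TP 25 / FP 12 — sizes at which the exact
engine, not the Monte Carlo fallback, is exercised), and mixed
demonstration cohorts of 1 000–2 000 proteins. Exact-engine verification
grids are exhaustive: all `(N, K, n, L)` with `N ≤ 60` against a rational
oracle, all `N ≤ 12` against subset enumeration, all 2x2/2x3 tables with
total ≤ 12 against a brute-force enumerator.

Percentages in the text reports round half-up (integer percent for
coverage, two decimals for assignment shares). Report files are TSV/blocked
text with LF endings; a JSON mirror of the statistics and a manifest with
input SHA-256 checksums accompany every run.

## Known limitations

- Keyword-based localization inherits Swiss-Prot's annotation gaps; absence
  of a compartment keyword is treated as "unknown", never as evidence of
  absence.
- Raw per-compartment p-values (the default) imply ~0.6 expected false
  flags per motif side at `alpha = 0.05` across twelve compartments; use
  the correction option when assignments feed downstream analyses
  sensitive to false positives.
- The Monte Carlo fallback reports a standard error but the pipeline's
  significance call still compares the point estimate to `alpha`.
- `tp_eq_fp` classification considers the *sets'* compartment unions, so a
  motif whose TP and FP sets each span the same two compartments is
  `testable`, not `tp_eq_fp`; only single-compartment identity is
  degenerate.
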