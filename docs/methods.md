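# Methods

## The quantity being estimated

Every statistic in `seedviab` is a functional of a *read-count-weighted
viability distribution*. Given a table of unique small-RNA sequences
with per-sample counts, each sequence is assigned the 6mer seed at
1-based positions 2–7 of the guide strand and the seed's percent
viability — the arithmetic mean of three cell-line viabilities for the
configured species (human or mouse). Viability is kept on the percent
scale; values above 100 are legal (growth-enhancing seeds). Sequences
are normalized to the RNA alphabet (T→U, uppercased) at ingestion so
that DNA-space sequencing reads and RNA-space seed nomenclature share
one key space.

The unit of the box statistics, group comparisons and composition
matrices is the **expanded multiset**: each row contributes
`round(weight / divisor)` copies of its viability, with weight either a
(group-mean) normalized read count or an absolute delta read count, and
divisor 1000 by default. Rounding is half-away-from-zero; rows rounding
to zero copies are dropped and counted in the log. `divisor=1` recovers
exact per-read weighting when needed. This makes a median a *median
viability per sequenced read*, not per distinct sequence.

## Pipeline stages and their parameters

- **Adapter trimming** (`preprocess.trim_adapter`): leftmost exact match
  of the 3' adapter, allowing a terminal partial match of at least
  `min_overlap` (default 4) nt. No mismatch tolerance — deliberate, so
  the trimmer is a deterministic, testable function; error-tolerant
  trimming is out of scope. Quality scores are ignored throughout:
  the analysis is count-based. Trimmed inserts shorter than 7 nt carry
  no seed and are dropped with a per-sample count.
- **Rare-read filter** (`min_total`, default 6): rows with total count
  across all samples below the threshold are removed. The rule operates
  on the all-sample total (not per-sample) and is inclusive at the
  boundary; it is logged and overridable.
- **Annotation**: exact-substring containment against reference sets in
  fixed priority order artificial > miRNA > RNAworld; ties within a set
  resolve to the first record in file order. Substring containment
  replaces alignment-based matching against curated lists: it is the
  deterministic core of a membership query, at the price of missing
  mismatched/isomiR variants — a documented divergence. Reads matching
  an artificial reference are removed; unmatched reads are *kept* as
  `unknown` (the analysis is gene-agnostic; every read ≥ 7 nt has a seed
  and viability).
- **Normalization**: each sample column scaled to 1,000,000 reads.
  All-zero columns stay zero with a warning.
- **Differential selection**: per-row two-sided equal-variance Student
  *t*-test on normalized counts, α = 0.05 by default, **no
  multiple-testing correction** — the per-row p < α rule is the stated
  selection criterion and is reported as such in the output metadata
  rather than silently corrected. The test is isolated behind one
  function; Welch's test is available via `test="welch"`. Each group
  needs ≥ 2 samples (within-group variance). Rows constant at the same
  value in both groups carry no evidence and are skipped (logged); rows
  with zero within-group variance but unequal means have an infinite
  *t* and are retained with p = 0. Retained rows are expressed as delta
  read counts Δ = mean(perturbed) − mean(control), with |Δ| the weight
  of the enriched (Δ > 0) and depleted (Δ < 0) series.
- **Box statistics**: quartiles by linear interpolation between order
  statistics (the common plotting default; recorded in the manifest
  because hinge values depend on the convention). Whiskers extend to
  the most extreme point no further than 1.5 × IQR beyond the hinges;
  points beyond are outliers.
- **Group comparison**: the Kruskal–Wallis rank-sum test with tie
  correction on the expanded multisets. When all values across groups
  are identical no effect is estimable and (H = 0, p = 1) is returned
  with a warning. The phrase "median test" sometimes denotes Mood's
  test; the rank-sum reading is used here and the choice is kept behind
  `compare_groups` should the alternative ever be wanted.
- **Binned curves**: rows are first collapsed on (seed, RNA type) by
  summing weights, then collapsed weights are aggregated into
  left-closed right-open viability bins of 1% anchored at 0 and
  extending past 100 when needed. Bin totals conserve the collapsed
  total exactly. No smoothing is applied; smoothing is presentation,
  not analysis.
- **Composition matrices**: weighted relative frequencies of A/C/G/U at
  seed positions 1–6, computed from integer expansion copies without
  literal replication but required (and tested) to equal the literal
  tally. Rendered, optionally, as a stacked-bar logo.

## The synthetic generator

`synthetic.gen_viability_table` emulates the structure of the 4096-seed
viability screen: per-cell-line viability = base(seed) + N(0, 8²),
clipped at 0, with base = 105 − 12·(#G) − 5·(#C). The functional form is
a modeling choice whose only load-bearing property is that viability
decreases monotonically in G-weighted G/C content (G-rich seeds toxic);
the exact slope is irrelevant to the pipeline's contracts.

`synthetic.gen_counts` draws one unique read per sampled seed (seed at
positions 2–7, random flanks, lengths 18–24 nt), assigns RNA types at
fractions 0.5 miRNA / 0.25 RNAworld / 0.05 artificial (remainder
unknown) — miRNAs dominating RISC content as they do in real Ago
pulldowns — lognormal(3, 1.5) baseline abundances for a realistic
heavy-tailed library, and tilts the perturbed group's expected loading
by exp(shift·(50 − viability)/25) before renormalizing. Counts are
Poisson around group means scaled to the target depth. Defaults — three
samples per group, 10⁵ reads per sample, 300 distinct sequences — are
the simulation conditions used throughout the tests and the acceptance
script; they keep replicate experiments cheap while leaving the
injected effect comfortably detectable at shift 0.8 and invisible at
shift 0.

What the generator does **not** emulate: overdispersion beyond Poisson
(the differential stage is a t-test on normalized values, so negative
binomial realism adds nothing to the contracts being validated),
ligation bias, PCR duplication, isomiR end heterogeneity, and realistic
miRNA nomenclature. Passing tests therefore demonstrate the pipeline's
internal correctness and its ability to recover a planted
seed-composition shift — not robustness to real-library dispersion.

Two generator details exist purely so that inverse-pair contracts are
exact: simulated reads never contain the (aperiodic) adapter, and no
read is a substring of another, which guarantees FASTQ → count-table
round-trips and exact recovery of planted annotations by substring
matching.

## miRNA-list entry mode

For reanalyzing published differential miRNA lists, a two-column CSV
(name, value) is annotated directly from the mature-miRNA reference:
the seed is read from positions 2–7 of the stored sequence. The sign of
the value encodes direction (positive = upregulated) and |value| is the
expansion weight, giving weighted box statistics and composition
matrices per direction and a Kruskal–Wallis comparison between them.

## Numerical and degenerate-input conventions

- Expansion of an empty or all-sub-threshold table yields an empty
  multiset; box statistics on it raise, and the orchestrator skips the
  affected group with a warning rather than aborting the run.
- Outputs are written with a fixed float format (`%.10g`), making full
  runs byte-for-byte reproducible from config + inputs; the manifest
  records every config value, input SHA-256, package version and a
  dropped-row accounting (short reads, artificial matches, rare reads,
  constant differential rows, zero-copy expansions).
- All randomness flows from a single seed per generator call; no global
  RNG state is used.

## Known limitations

- Substring matching cannot annotate reads with sequencing errors or
  non-templated additions; they fall into `unknown` (and are still
  analyzed, since the statistics are annotation-agnostic).
- The per-row t-test on n = 2–4 samples per group has the usual small-n
  caveats; the package reports uncorrected p-values by design and is
  not a general-purpose differential-expression tool.
- Viability lookups must be complete (4096 seeds); partial tables are
  rejected rather than imputed.
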