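# Methods

This note records the models, parameter choices and numerical conventions
behind `mitagprofiler`, and what the synthetic-data tests do and do not
demonstrate about real data.

## The estimator

The quantity of interest is the relative cell abundance `p_t` of each
taxon *t* in a community profiled through its ribosomal operon. Reads
recruited to reference gene *g* of taxon *t* arrive, in expectation,
proportionally to `p_t · c_t · L_{t,g}` — cell fraction × operon copy
number × gene length. The estimator inverts exactly that model:

```
w_t = Σ_g n_{t,g} / (L_{t,g} · c_t),     p̂_t = w_t / Σ_u w_u
```

Counts from 16S, 23S and 5S are summed after length correction and before
the copy-number division, because the three genes sit on one operon and
share `c_t`; summing uses all recruited reads rather than privileging one
gene. The estimator is scale-invariant in the counts and undoes the copy
bias exactly when `c_t` is correct; a wrong copy number propagates
linearly into `p̂_t`.

Copy numbers, when not known per genome, come from a name → mean-copies
table queried at the most specific rank available along the lineage and
rounded half-up. Half-up is a convention (4.5 → 5); the rounding itself
matters more than its direction, since fractional copies are not
physical. Both the table and the rounding are caller-replaceable.

## Read preparation

Mate pairs are merged by scanning candidate overlaps in
`[min_overlap, max_overlap]` (defaults 10 and the expected insert size,
175), scoring each by mismatch ratio, and accepting the lowest-ratio
overlap (ties to the longer) when the ratio is ≤ 0.25. These numeric
defaults follow the FLASH merger's published defaults, except the
maximum overlap, which FLASH derives from the read length and expected
fragment size; here it defaults to the configured insert mean.
Disagreeing positions take the higher-quality base (ties keep the forward
read); N counts as a mismatch. A consequence worth knowing: pairs from
inserts longer than `2·read_length − min_overlap` (206 bp at defaults)
cannot merge and are discarded — with the default truncated-normal insert
model (mean 175, σ 15, floor at the read length) that is ~2% of pairs,
and the loss is taxon-independent so it does not bias the profile.

Trimming with `bad_fraction = 0` returns the longest contiguous run free
of bases below the quality cutoff (default Q13, the permissive end of
common trimmers; configurable) and discards reads shorter than
`min_length` (default 90). For `bad_fraction > 0` a sliding window keeps
the bad-base fraction within tolerance; the strict setting is the one the
pipeline uses and the one tested exhaustively.

## Recruitment

Each cleaned read is aligned semi-globally against both strands of every
reference gene. Implementation: exact 15-mer seeding at stride 20 (plus
the read tail) proposes (gene, diagonal) candidates; each candidate is
verified with an edit-distance alignment (edlib, infix mode) in a window
padded by 8 bp, and identity is computed as matched columns over all
aligned columns, gaps included. The seeding is lossless for the
thresholds in use: a read passing 98% identity at ≥90 bp contains an
error-free stretch ≥ 39 bp ≫ the seed length, so a true placement always
fires a seed. Equivalence with an exhaustive all-offsets Hamming scan is
asserted in the tests for the no-indel case.

"Alignment coverage" is the fraction of the **read** aligned, not of the
gene: reads (~157 bp merged) are far shorter than the genes, so a
gene-fraction denominator would reject everything. A read overhanging a
gene end is clipped to its in-gene part, which lowers its coverage — a
108 bp read with 54 bases inside the gene sits exactly at the 50%
boundary and is kept (thresholds are inclusive).

Each read keeps at most one hit, the best by (identity, aligned length,
lexicographically smallest taxon id). Best-hit-only assignment makes the
counts partition the read pool. The deterministic tie-break means reads
from a region identical between two references are always credited to
the same (alphabetically first) taxon; at the divergences the generator
produces (≥1% between any pair) this shifts at most a few tenths of a
percentage point and is visible, and bounded, in the recovery tests.

## The coverage-homogeneity artefact rule

Conserved fragments of a gene absent from the community can recruit reads
convincingly by identity yet cover only a short segment of the reference.
The test formalises "reads do not homogeneously cover the gene" as:
reject when breadth (covered fraction of positions) is **strictly below**
0.5, or when ≥95% of aligned bases fall in one contiguous covered block
spanning <20% of the gene. The three constants are this package's
quantification of a qualitative criterion and are all configurable; the
reference case — reads confined to positions ~850–1,000 of a full-length
16S, breadth ≈ 0.08 — is rejected by either clause. Genes shorter than
the 100 bp window (5S at 115 bp passes; anything shorter) are exempted in
the pipeline wrapper rather than erroring.

## Taxonomy collapsing

Leaves are sorted by decreasing abundance (ties by name); the minimal
prefix whose cumulative share reaches the significance level (default
0.95) is flagged significant, including the leaf that crosses the
threshold. Every insignificant leaf is folded into the significant leaf
with the deepest common ancestor — same rank preferred, then higher
abundance (snapshot at pass start), then lexicographically smaller name —
and the pass repeats until no leaf is insignificant. The iteration is
deliberate: a single pass is not a fixed point, because mass folded into
high-abundance leaves can push a late significant leaf out of the 95%
prefix; iterating makes the operation idempotent, which the tests verify
on 1,000 random ragged trees along with exact abundance conservation.
Entropy never increases under collapsing (merging mass is entropy-
reducing), also verified empirically.

## Pathway calling

Annotation rows are filtered at percent identity ≥ 0.60 and a pathway is
present when ≥ 0.80 of its required genes are detected; both thresholds
are inclusive at the boundary, reading "cut-off" and "when 80% were
detected" as attained-at-boundary, and both are configurable. Detection
is binary per distinct gene symbol; read support sums across ORFs and is
reported alongside on a `log10(1 + n)` scale. The shipped bundle defines
each pathway as a flat required-gene set (no AND/OR module logic — a
stated non-goal); subunits are separate entries (dsrA, dsrB, dsrC). Genes
genuinely shared between pathways (frdA/frdB in the reductive citric acid
cycle and in fumarate respiration) couple those two completeness cells:
detecting the gene for either pathway counts for both.

## The synthetic-data generator

The generator defines the study conditions; it is not tuned per test.

- **Community**: seven dominant taxa at cell fractions 0.300, 0.220,
  0.140, 0.130, 0.095, 0.060, 0.047 plus one minor taxon at 0.008, with
  operon copy numbers 3, 5, 2, 4, 1, 1, 2 and 11 — a low-diversity
  sulphidic-lake assemblage with the copy-number spread that makes the
  correction matter.
- **Operons**: genes of exactly 1,819 / 3,731 / 115 bp (16S/23S/5S)
  derived from one uniform-random ancestor by point substitutions only.
  Each taxon mutates its own disjoint set of 16S positions, so pairwise
  identity is exactly `1 − (m_i + m_j)/L` and provably inside the
  requested 0.83–0.99 band; no-indel construction is what makes the
  divergence contract verifiable. Disjointness caps the taxon count
  (~22 in that band); wider requests fail loudly. 23S/5S fall back to
  independent positions if disjointness is impossible there.
- **Reads**: 2×108 bp innie pairs from truncated-normal inserts
  (mean 175, σ 15, floor 108, cap `min(gene, 215)`), pair counts
  multinomial with weights `cell_fraction × copies × length` — the bias
  normalisation must undo is built into the generator, not bolted on.
  Per-base substitution errors at 0.1% (the run's true error profile is
  unknown; this is a choice in the realistic range for the platform),
  with error positions downgraded to Q8 with probability 0.5 so trimming
  has something to act on. Quality is otherwise constant Q37.
- **Ground truth**: a TSV mapping read id → (taxon, gene, start, strand)
  enables exact sensitivity/misassignment scoring.
- **Annotation tables**: per (taxon, pathway, fraction) exactly
  `round(fraction × n_genes)` distinct genes get a row with identity in
  [0.60, 1.0]; optional decoy rows for unplanned genes get [0.40, 0.60)
  so the identity filter removes real rows. Identities for planned rows
  start at the filter threshold on purpose — the planned-completeness
  contract must survive the default filter.

What passing tests show — and what they do not: the generator has no
indels, chimeras, contaminant background, inter-operon intragenomic
variation, or GC-dependent coverage bias. Recovery within ±2 points under
these conditions demonstrates that the pipeline's own arithmetic and
thresholds are unbiased; it does not bound the error on real libraries,
where copy-number estimates from database relatives are themselves
approximate.

## Problem sizes and determinism

The recovery analyses run at ~53k read pairs (`depth=3000`), where
per-taxon binomial noise is ≈0.2 points — an order of magnitude inside
the ±2-point recovery band, so conclusions are not scale-limited;
threshold and decoy checks use 1,000 reads; collapsing properties use
1,000 random trees. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; simulation outputs are byte-identical
under a fixed seed, and the pipeline's JSON summary is byte-identical
under a fixed config (floats rounded to 6 decimals before writing).

## Known limitations

- Copy-number correction treats `c_t` as exact; no uncertainty
  propagation.
- The recruitment identity model (unit-cost edit distance, identity over
  columns) is one of several defensible conventions; BLAST-style scoring
  would differ slightly near the 98% boundary.
- The evenness printed by some field studies on comparable profiles is
  not reproducible as Pielou's `J` from their printed abundances; this
  package reports Pielou and makes no claim of matching such values.
- Pathway logic is flat gene sets; isoenzymes and alternative modules
  need explicit extra entries.
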