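# mitagprofiler

Copy-number-corrected community profiling and taxon-resolved pathway
calling for low-diversity shotgun metagenomes, built around rDNA *miTAGs* —
ribosomal-gene reads identified directly in the shotgun read pool, with no
PCR amplification step.

## The problem

In a low-diversity community (the motivating case is an anoxic, sulphidic
subglacial-lake water column with ~7 dominant genera), full-length
16S/23S/5S rRNA operons can be assembled per taxon and used to recruit the
ribosomal fraction of the raw reads at high stringency. Raw recruitment
counts are a biased estimator of community structure, for two reasons:

1. **Gene length** — a 3,731 bp 23S gene sheds about twice the fragments
   of a 1,819 bp 16S gene at equal abundance.
2. **rDNA operon copy number** — genomes carry 1–12 operon copies, so a
   12-copy cell contributes 12× the reads of a single-copy cell.

`mitagprofiler` turns recruitment counts `n_{t,g}` (taxon *t*, gene *g*)
into relative abundances by

```
w_t = Σ_g  n_{t,g} / (L_{t,g} · c_t)        p_t = w_t / Σ_u w_u
```

where `L_{t,g}` is the reference gene length and `c_t` the operon copy
number (estimated, when not known, by rounding the mean copy number at the
most specific taxonomic rank available in a copy-number table). The
profile is summarised with Shannon diversity `H = −Σ p_t ln p_t` and
Pielou evenness `J = H / ln S`.

Around that core the package implements the full analysis chain:

- **Read preparation** — FLASH-style overlap merging of 2×108 bp innie
  pairs from ~175 bp inserts (best overlap by mismatch ratio, consensus by
  base quality), then strict quality trimming (`minlength 90`,
  `badfraction 0`: no base below the cutoff survives).
- **Recruitment** — semi-global alignment of each cleaned read against
  both strands of every reference gene; a hit requires ≥98% identity over
  the aligned columns and ≥50% of the read aligned, and each read keeps
  only its best hit so counts partition the pool.
- **Coverage-homogeneity artefact test** — a reference recruited only
  over a short segment (low breadth, or ≥95% of aligned bases inside one
  block spanning <20% of the gene) is flagged as a conserved-fragment
  artefact and excluded; this is how spurious "archaeal" 16S fragments
  that pile onto positions ~850–1,000 of a full-length gene are rejected.
- **Taxonomy collapsing** — leaves of a rank-labelled lineage tree are
  sorted by decreasing abundance; the minimal prefix holding ≥95% of the
  total is kept and every other leaf is folded into the significant leaf
  with the deepest common ancestor (same rank preferred).
- **Pathway calling** — ORF annotation rows are filtered at ≥60% amino
  acid identity; a pathway is present in a taxon (or the pooled
  community) when ≥80% of its required genes are detected. An editable
  bundle of chemolithoautotrophy pathways ships with the package
  (Wood–Ljungdahl, reductive TCA, sulphur and nitrogen cycling,
  hydrogenases, and more).
- **Synthetic data** — a mock-community generator produces operon
  references with controlled pairwise divergence (83–99% 16S identity),
  paired FASTQ reads with the length × copy-number bias built in, ground
  truth per read, and annotation tables with planned per-cell pathway
  completeness — so every stage is testable without downloads.

## Worked example

```python
import mitagprofiler as m

community, refs = m.demo_community(seed=7)          # 7 dominant + 1 minor taxon
cfg = m.SimulationConfig(depth=3000, seed=7)        # ~53k read pairs
pairs, truth = m.simulate_reads(community, refs, cfg)

cleaned, stats = m.prep_reads(pairs)                # merge + trim
hits = m.recruit(cleaned, refs)                     # ≥98% id, ≥50% coverage
profile = m.normalise(m.hits_to_counts(hits), refs)

for taxon, p in sorted(profile.relative_abundance.items(),
                       key=lambda kv: -kv[1]):
    print(f"{taxon:22s} {100 * p:5.1f}%  (truth {100 * community.fractions[taxon]:.1f}%)")
print(m.diversity(profile))
```

Output:

```
Sulfuricurvum           29.3%  (truth 30.0%)
Acetobacterium          22.5%  (truth 22.0%)
Sulfurospirillum        13.7%  (truth 14.0%)
Geobacter_Pelobacter    12.6%  (truth 13.0%)
Saccharibacteria        10.2%  (truth 9.5%)
Caldisericum             6.2%  (truth 6.0%)
Prolixibacteraceae       4.7%  (truth 4.7%)
Desulfosporosinus        0.8%  (truth 0.8%)
DiversityStats(shannon_H=1.817257415738218, richness_S=8, pielou_J=0.8739160872347402)
```

Every estimate lands within ±0.7 points of the true cell fraction. Without
copy-number correction the same counts put the 5-copy acetogen at ~35%
(13 points off) — the correction is what makes the profile quantitative.

The same chain is available from the shell:

```bash
mitag run --seed 7 --depth 3000 --out-dir demo_out   # writes summary.json + TSVs
mitag simulate --seed 7 --out-dir sim                # FASTQ + references + truth
mitag prep sim/reads_R1.fastq sim/reads_R2.fastq --out-dir prep
```

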