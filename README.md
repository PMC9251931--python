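# txdepth

How does sequencing depth shape what a transcriptome assembler recovers —
and why do coding and noncoding transcripts behave so differently?

`txdepth` is a tested evaluation framework for that question, aimed at
people who benchmark reference-based transcript assembly (bulk short-read,
subsampled long-read, and assembly-guided single-cell quantification). It
provides:

- **Reference-based assembly evaluation** — intron-chain matching
  (gffcompare-style `=` semantics: exact junction identity on the same
  strand, free terminal-exon outer boundaries), exon/splice completeness per
  reference transcript, class-stratified sensitivity and precision,
  annotated/variant/novel classification, transposable-element (TE) overlap,
  and recurrence filtering across samples.
- **Saturation statistics** — Spearman rank correlation of depth vs
  transcript count, degree-1 tricube loess fits with SE bands, per-depth-step
  increment tables, depth binning, coding:noncoding ratio curves, and
  per-group observed−predicted deviations.
- **Expression-ranked cumulative curves** — cumulative expression share,
  cumulative precision with A/B/C percentile classes, cumulative
  coding:noncoding ratio.
- **Single-cell detection statistics** — median-of-ratios normalization,
  per-transcript detection rates and expression CVs, tag-count vs detection
  correlations, and paired comparison of two guiding assemblies.
- **A synthetic transcriptome/assembly simulator** that generates a
  two-class ground-truth panel (coding transcripts: higher expression, lower
  TE content, lower novelty) and simulates depth-dependent assembly with
  junction-level dropout, read-pool merging/partitioned subsampling, and
  sparse single-cell count matrices — so every statistic above is testable
  end-to-end without any external data.

## The core quantities

For a reference transcript *R* with junction set *J(R)* and a query
assembly *Q*:

- *splice completeness* = 100 · |J(R) ∩ J(Q, same chrom/strand)| / |J(R)|
- *exon completeness* = 100 · (exons of *R* recovered in the best-matching
  query transcript) / |exons(*R*)| (internal exons: both boundaries exact;
  terminal exons: splice-side boundary only)
- *correctly assembled* ⇔ some query transcript has an identical intron
  chain (single-exon: same-strand reciprocal overlap ≥ 0.9)
- *sensitivity* = correctly assembled reference transcripts / reference
  transcripts; *precision* = reference-matching query transcripts / query
  transcripts, per coding class
- *saturation* is quantified as the per-step increment of a loess fit
  f: increment_i = f((i+1)·s) − f(i·s), with s one grid step of reads.

## Worked example

```python
from txdepth.study import run_depth_ladder
from txdepth.assembly_compare import filter_assembly
from txdepth import saturation

run = run_depth_ladder(seed=1)          # 5,000-transcript panel, 37 samples
series = saturation.depth_series_from_assemblies(
    [filter_assembly(s.assembly) for s in run.samples]
)
print(series.groupby("depth")[["n_coding", "n_noncoding"]].mean())
print(saturation.spearman_rho(series["depth"], series["n_noncoding"]))
```

prints (seed 1):

```
          n_coding  n_noncoding
depth
100000      1180.0        173.3
200000      1763.2        401.4
500000      2412.2        874.8
1000000     2690.0       1269.0
2000000     2795.0       1605.0
0.9068388559017296
```

Out of 3,012 coding and 1,988 noncoding ground-truth transcripts, a
0.1M-read sample assembles 39% of the coding but only 9% of the noncoding
panel; by 2M reads coding counts have nearly saturated (93%) while
noncoding counts are still climbing (81%) — the coding:noncoding ratio
falls from 6.8 to 1.7 across the ladder. The full analysis sequence lives
in `analysis/01_simulate.py` … `analysis/05_single_cell.py`; each script
states what it computes and writes tidy tables under `results/`.

The command-line interface exposes the same steps
(`txdepth simulate | compare | saturate | curves | sc`).

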