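# Methods

## Scope and design

`txdepth` studies how sequencing depth affects the recovery of coding vs
noncoding transcripts in reference-based transcript assembly. Because the
interesting statistics (sensitivity, precision, completeness, saturation
curves) all require ground truth, the package pairs its evaluation modules
with a synthetic transcriptome/assembly simulator: the simulator defines a
known two-class panel and a depth-dependent detection process, and every
downstream statistic is computed exactly as it would be on real
assemblies — the pipeline never peeks at the truth maps except where a
truth-dependent flag (e.g. the `matched` indicator of precision curves) is
itself the quantity under study.

## The synthetic reference panel

`generate_reference` draws `n_transcripts` transcripts placed left-to-right
on a small synthetic genome (4 × 40 Mb by default) with random intergenic
gaps, so exon chains never self-overlap by construction. Per transcript:

| parameter | default | meaning |
|---|---|---|
| `coding_fraction` | 0.6 | P(coding) |
| `expression_log_mean` | 1.5 coding / 0.0 noncoding | natural-log mean of log-normal expression |
| `expression_log_sd` | 1.0 both | log-normal sd |
| `te_probability` | 0.25 coding / 0.65 noncoding | P(TE-containing) |
| `novel_fraction` | 0.05 coding / 0.30 noncoding | P(novel), else annotated |
| `exon_count_lambda` | 4.0 | exons = 1 + Poisson(λ) |
| exon / intron lengths | log-normal, median 150 / 1500 nt | clipped at 30 / 60 nt |

The class contrasts encode the well-established biology of the system:
coding mRNAs are more highly expressed, less TE-derived and better
annotated than lncRNAs. The magnitudes are chosen so the contrasts are
detectable in panels of a few thousand transcripts; they are a study
condition, not a fit to any dataset.

## The detection (assembly) model

Read pools are represented as per-transcript integer read counts — the
sufficient statistic for everything downstream — drawn multinomially with
weight `expression × length` at a given depth. Per transcript, every splice
junction and every exon boundary is a *feature* with a boundary-anchor
window of 50 nt: out of the transcript's `n` reads, a feature's support is
Binomial(n, window/length)-thinned and the feature is detected when the
support reaches `k` (default 2). A transcript is emitted in full — and is
then correctly assembled by construction — iff all junctions are detected
and `n ≥ m` (default 3); otherwise the detected exon subset, if any, is
emitted as a partial transcript. Spurious transcripts with intron chains
absent from the panel are added at `noise_rate` (default 20) per million
reads, predominantly noncoding (`noise_coding_prob` 0.2). Small fractions
of emitted transcripts are made strandless (0.02) or truncated below 200 nt
(0.02) so the confidence filter (discard unstranded or < 200 nt) has real
work to do.

Two modelling choices deserve emphasis:

**Feature coherence.** The features of one transcript share a Gaussian
coverage latent with correlation `detection_correlation` (default 0.9):
each feature's detection indicator is `Φ(√ρ·z_t + √(1−ρ)·z_f) <
P(support ≥ k | n)`, which preserves the Binomial-thinned marginal while
making features of a transcript stand or fall together. This reflects how
real coverage behaves — library preparation, mappability and GC effects hit
whole transcripts, not individual junctions — and it is what produces the
strongly bimodal exon completeness (transcripts mostly at exactly 0% or
exactly 100%) that real assemblies show. Fully independent per-feature
dropout would instead produce a broad band of partially assembled
transcripts, which assemblers do not emit.

**Sample-free detection latents.** The latents are keyed by
(seed, transcript_id), *not* by sample, so detection is a deterministic,
monotone function of the read-count vector. Pooling two samples' reads can
therefore only add correctly assembled transcripts, and partitioned
subsampling interacts with detection exactly as splitting a real read pool
would. Replicate-to-replicate variability comes from the multinomial count
draws; the latent is a transcript-intrinsic "difficulty", which slightly
understates between-replicate variance of per-transcript detection.

All randomness flows through counter-based Philox streams keyed by hashed
(seed, context) tuples, so results are platform-independent and any
individual draw can be replayed by a test oracle without running the
simulator.

## What the simulator does and does not emulate

Emulated: depth-dependent recovery with earlier coding saturation; bimodal
exon/splice completeness; depth-increasing noise (falling precision);
class-skewed TE content and novelty; disjoint read-pool partitions and
merges; sparse single-cell counts with per-cell depth variation and
expression-dependent dropout. Not emulated: base-level read sequences and
sequencing error; fragment-length and positional (3'-bias beyond the
dropout abstraction) effects; inter-transcript genomic overlap and shared
exons between isoforms; assembler-specific heuristics. Passing tests
therefore demonstrate that the *statistics* behave correctly on data with
the stated structure, not that any particular assembler achieves these
numbers on real reads.

## Matching semantics

"Correctly assembled" is exact intron-chain identity on the same strand;
terminal exon outer boundaries are free (junctions are what short-read
assembly determines reliably). Single-exon transcripts, having no
junctions, fall back to same-strand reciprocal overlap ≥ 0.9
(configurable); their exon and splice completeness are defined as 100 when
that rule matches and 0 otherwise. Exon completeness is scored against the
single best-matching query transcript — exact chain match wins outright,
else most shared junctions, ties broken by shared exon boundaries then
lexicographic id. Precision counts each query transcript at most once. A
query transcript is *annotated* if it chain-matches the annotation, *novel*
if none of its exons overlaps any annotated exon on either strand, and
*variant* otherwise. One published description of the false-positive
definition for this kind of sensitivity analysis is self-contradictory
(it would make matching transcripts the false positives); we use the
standard definition: a query transcript that matches no reference
transcript is a false positive.

## Numerical choices

- **Loess**: degree-1 local regression, tricube weights over the
  span-nearest neighbours (span 0.75 default), no robustness iterations;
  fits agree with `statsmodels` lowess to ~1e-15. The local solve uses a
  pseudoinverse so that degenerate neighbourhoods (all remaining weight on
  one depth value, common in tie-heavy replicate designs) reduce to a local
  constant fit; when every neighbour sits exactly at the cutoff distance
  (all tricube weights zero) the weights fall back to uniform. The SE band
  is `σ̂·‖l‖` with `l` the equivalent-kernel weights and `σ̂` the global
  residual sd. Predictions outside the observed depth range are clamped to
  the boundary value; increment grids start at 0 reads where no data exist,
  so the first grid steps inside the clamped region are zero and saturation
  scans skip them. On the 20/10/4/2/1 ladder, whose five distinct depths
  defeat span-0.75 neighbourhoods, the analysis scripts use span 1.0.
- **Undefined values** (coding:noncoding ratio with zero noncoding,
  precision with an empty query, Spearman on a constant vector, CV with
  zero mean) are reported as missing/`None`, never coerced to 0 or ∞.
- **Ranked curves**: ties in expression are broken by transcript_id, and
  the cumulative denominator is the prefix total, so curves are
  deterministic, end at exactly 100%, and equal a sequential prefix-scan
  bit for bit. Percentile classes use rank thresholds `r ≤ ⌈b·n/100⌉`
  (boundaries 30/60), so a singleton list is all class A and n = 10 splits
  3/3/4.
- **Median-of-ratios size factors** follow the standard procedure
  (per-cell median over reference transcripts of count / per-transcript
  geometric mean). Factors are defined up to one global constant; the
  equivariance guarantee (scaling one cell's counts by c scales its factor
  by c) holds exactly for factor *ratios*. When no transcript is nonzero in
  all cells, a flagged sparse fallback uses transcripts nonzero in ≥ 50% of
  cells with positive-count geometric means.
- **Detection threshold** in single-cell data is raw count ≥ 1
  (configurable); CVs are computed over detecting cells by default because
  zero inflation otherwise dominates (`cv_mode="all"` switches this). Mean
  normalized expression is likewise reported over detecting cells. CVs are
  reported per class without further interpretation.

## Study conditions

The analysis scripts and the acceptance script run a desk-scale version of
a depth-ladder experiment: a 5,000-transcript panel; depths of 0.1, 0.2,
0.5, 1 and 2 million read pairs with 20, 10, 4, 2 and 1 replicates
(37 samples); increment grids in 0.1M-read steps; 500 cells with log-normal
tag totals (median 5,000) for the single-cell arm. These sizes keep a full
run under a minute on one CPU while preserving the replicate structure of
the design they scale down (a 10–200M-read ladder, ÷100). Subsample-size
inputs are explicit read counts; scale is always the caller's choice.

## Known limitations

- Detection latents shared across samples make per-transcript recovery
  strongly correlated between replicates; replicate SDs of completeness
  percentages are accordingly small.
- The simulator emits at most one partial transcript per reference
  transcript per sample and never fragments a transcript into several
  pieces.
- Single-exon recurrence clustering is greedy (longest member as
  representative), which can split borderline overlap chains differently
  than a global clustering would.
- Loess SE bands use a global residual variance; heteroscedastic counts
  (variance growing with depth) make the band approximate.
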