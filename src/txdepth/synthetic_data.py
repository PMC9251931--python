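"""Synthetic transcriptomes and depth-dependent assembly simulation.

The generator emulates the study system: a two-class transcriptome in which
coding transcripts have higher expression, broader recurrence across samples
and lower transposable-element content than noncoding ones, and a
depth-dependent assembler whose junction-level dropout makes reference
transcripts either fully recovered or entirely missed at a given depth.

Detection model
---------------
Reads are allocated to transcripts multinomially with weight
``expression x length`` (read pools are kept as per-transcript integer
counts, which are sufficient statistics for everything downstream). Each
splice junction and each exon boundary of a transcript is a *feature* with a
boundary-anchor window of ``anchor_window`` nt: out of the transcript's
``n`` reads, the feature's support is Binomial(n, window/length)-thinned,
and the feature is detected when its support reaches
``junction_detect_threshold`` (k). Features of one transcript share a
Gaussian coverage latent with correlation ``detection_correlation``:
library preparation and mappability affect a whole transcript at once, so
features are detected or missed largely together, which is what produces the
strongly bimodal exon completeness seen in real assemblies. A reference
transcript is emitted in full (correctly assembled) iff all junctions are
detected and its read count reaches ``transcript_detect_threshold`` (m);
otherwise, if at least one exon is detected, the detected exon subset is
emitted as a partial transcript. Spurious (noise) transcripts with intron
chains absent from the panel are added at ``noise_rate`` per million reads.

Detection latents are keyed by (seed, transcript_id) — not by sample — so
detection is a deterministic, monotone function of the read-count vector.
Merging samples or subsampling reads therefore interacts with detection
exactly as pooling or splitting real read sets would: a merged pool can only
gain correctly assembled transcripts.

All randomness flows through keyed counter-based streams (see ``_rng``), so
any draw can be replayed independently by tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import binom

from ._rng import substream
from .types import (
    CODING,
    NONCODING,
    NOVEL,
    ANNOTATED,
    UNSTRANDED,
    Assembly,
    GenomicInterval,
    SampleMeta,
    TranscriptRecord,
)

NOISE = "NOISE"

_panel_counter = itertools.count()


@dataclass
class SimulationConfig:
    """Parameters of the synthetic transcriptome and the detection model.

    Class-specific dictionaries are keyed by ``"coding"`` / ``"noncoding"``.
    Expression is log-normal per class; the default 1.5 natural-log gap in
    favour of coding transcripts, the higher noncoding TE probability and the
    higher noncoding novelty encode the qualitative contrasts of the study
    system at magnitudes detectable in panels of a few thousand transcripts.
    """

    n_transcripts: int = 10_000
    coding_fraction: float = 0.6
    expression_log_mean: dict = field(
        default_factory=lambda: {CODING: 1.5, NONCODING: 0.0}
    )
    expression_log_sd: dict = field(
        default_factory=lambda: {CODING: 1.0, NONCODING: 1.0}
    )
    te_probability: dict = field(
        default_factory=lambda: {CODING: 0.25, NONCODING: 0.65}
    )
    novel_fraction: dict = field(
        default_factory=lambda: {CODING: 0.05, NONCODING: 0.30}
    )
    # exon-chain geometry
    exon_count_lambda: float = 4.0  # n_exons = 1 + Poisson(lambda)
    exon_log_mean: float = math.log(150.0)
    exon_log_sd: float = 0.5
    min_exon_length: int = 30
    intron_log_mean: float = math.log(1500.0)
    intron_log_sd: float = 0.7
    min_intron_length: int = 60
    # genome to place transcripts on
    n_chroms: int = 4
    chrom_length: int = 40_000_000
    # detection model
    anchor_window: int = 50
    junction_detect_threshold: int = 2  # k
    transcript_detect_threshold: int = 3  # m
    detection_correlation: float = 0.9
    noise_rate: float = 20.0  # false transcripts per million reads
    noise_coding_prob: float = 0.2
    # fractions of emitted transcripts mangled to exercise filtering
    unstranded_fraction: float = 0.02
    truncate_fraction: float = 0.02
    # SampleMeta fractions
    mapped_fraction: float = 0.92
    assigned_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.coding_fraction, self.noise_coding_prob,
                  self.unstranded_fraction, self.truncate_fraction,
                  self.mapped_fraction, self.assigned_fraction,
                  *self.te_probability.values(), *self.novel_fraction.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.junction_detect_threshold < 1 or self.transcript_detect_threshold < 1:
            raise ValueError("detection thresholds k, m must be >= 1")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if not 0.0 <= self.detection_correlation < 1.0:
            raise ValueError("detection_correlation must be in [0,1)")


@dataclass
class ReferencePanel:
    """The ground-truth transcriptome the simulator assembles against."""

    transcripts: list[TranscriptRecord]
    genome: dict[str, int]
    uid: int = field(default_factory=lambda: next(_panel_counter))

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.expression <= 0:
                raise ValueError(f"non-positive expression for {t.transcript_id}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_id(self) -> dict[str, TranscriptRecord]:
        return {t.transcript_id: t for t in self.transcripts}

    def to_assembly(self, sample_id: str = "reference") -> Assembly:
        return Assembly.from_transcripts(
            self.transcripts, SampleMeta(sample_id=sample_id)
        )

    def annotated_assembly(self, sample_id: str = "annotation") -> Assembly:
        return Assembly.from_transcripts(
            (t for t in self.transcripts if t.annotation_status == ANNOTATED),
            SampleMeta(sample_id=sample_id),
        )


@dataclass
class SimulatedSample:
    """One simulated assembly plus its ground truth.

    ``truth_map`` maps every assembled transcript_id to the reference
    transcript it derives from, or ``NOISE``. ``read_counts`` is the read
    pool: reads per panel transcript, aligned with ``panel.transcripts``.
    ``fully_assembled`` is the set of reference ids emitted with their
    complete intron chain.
    """

    assembly: Assembly
    truth_map: dict[str, str]
    depth: int
    read_counts: np.ndarray
    panel: ReferencePanel
    seed: int
    sample_id: str
    fully_assembled: frozenset[str] = frozenset()


def generate_reference(config: SimulationConfig) -> ReferencePanel:
    """Draw a ground-truth transcriptome under ``config``.

    Transcripts are placed left-to-right on a small synthetic genome with
    random intergenic gaps; exons never overlap within a transcript by
    construction. Deterministic given ``config.seed``.
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {c: config.chrom_length for c in chroms}
    transcripts: list[TranscriptRecord] = []
    chrom_idx = 0
    cursor = 0
    for i in range(config.n_transcripts):
        tid = f"ref_{i:06d}"
        rng = substream(config.seed, "panel", tid)
        coding = rng.uniform() < config.coding_fraction
        cls = CODING if coding else NONCODING
        expression = float(
            rng.lognormal(config.expression_log_mean[cls], config.expression_log_sd[cls])
        )
        te = bool(rng.uniform() < config.te_probability[cls])
        status = NOVEL if rng.uniform() < config.novel_fraction[cls] else ANNOTATED
        n_exons = 1 + int(rng.poisson(config.exon_count_lambda))
        exon_lens = np.maximum(
            config.min_exon_length,
            np.round(rng.lognormal(config.exon_log_mean, config.exon_log_sd, n_exons)),
        ).astype(int)
        intron_lens = np.maximum(
            config.min_intron_length,
            np.round(
                rng.lognormal(config.intron_log_mean, config.intron_log_sd,
                              max(n_exons - 1, 1))
            ),
        ).astype(int)
        strand = "+" if rng.uniform() < 0.5 else "-"
        gap = int(rng.integers(500, 3000))
        span = int(exon_lens.sum() + intron_lens[: n_exons - 1].sum())
        while cursor + gap + span > genome[chroms[chrom_idx]]:
            chrom_idx += 1
            cursor = 0
            if chrom_idx >= len(chroms):
                raise ValueError(
                    "genome too small to place transcripts; increase "
                    "chrom_length or n_chroms"
                )
        chrom = chroms[chrom_idx]
        pos = cursor + gap
        exons = []
        for j in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cursor = pos
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=f"gene_{i:06d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                coding_class=cls,
                annotation_status=status,
                te_containing=te,
                expression=expression,
            )
        )
    return ReferencePanel(transcripts=transcripts, genome=genome)


# ---------------------------------------------------------------------------
# panel-level caches: geometry and detection latents


class _PanelArrays:
    """Vectorised per-feature geometry of a panel.

    Feature layout per transcript: junctions first (5'->3'), then exons.
    """

    def __init__(self, panel: ReferencePanel):
        lengths, n_feat, tidx = [], [], []
        for i, t in enumerate(panel.transcripts):
            lengths.append(t.length)
            nf = 2 * t.n_exons - 1
            n_feat.append(nf)
            tidx.extend([i] * nf)
        self.lengths = np.array(lengths, dtype=float)
        self.n_features = np.array(n_feat, dtype=int)
        self.offsets = np.concatenate([[0], np.cumsum(self.n_features)])
        self.feature_tidx = np.array(tidx, dtype=int)
        self.n_junctions = np.array([t.n_exons - 1 for t in panel.transcripts])
        self.weights = np.array(
            [t.expression * t.length for t in panel.transcripts], dtype=float
        )
        self.chains = {_chain_key(t) for t in panel.transcripts}


class _Latents:
    """Per-feature detection uniforms and per-transcript mangle draws."""

    def __init__(self, panel: ReferencePanel, arrays: _PanelArrays, seed: int,
                 rho: float):
        us, mangle = [], []
        s_t, s_f = math.sqrt(rho), math.sqrt(1.0 - rho)
        for t, nf in zip(panel.transcripts, arrays.n_features):
            rng = substream(seed, "latent", t.transcript_id)
            z = rng.standard_normal(1 + nf)
            us.append(ndtr(s_t * z[0] + s_f * z[1:]))
            mangle.append(rng.uniform(size=1)[0])
        self.u = np.concatenate(us) if us else np.empty(0)
        self.mangle = np.array(mangle)


_cache: dict[tuple[int, int, float], tuple[_PanelArrays, _Latents]] = {}


def _panel_state(panel: ReferencePanel, seed: int, rho: float):
    key = (panel.uid, seed, rho)
    if key not in _cache:
        if len(_cache) > 8:
            _cache.clear()
        arrays = _PanelArrays(panel)
        _cache[key] = (arrays, _Latents(panel, arrays, seed, rho))
    return _cache[key]


def _chain_key(t: TranscriptRecord):
    if t.n_exons == 1:
        return (t.chrom, t.strand, "single", t.start, t.end)
    juncs = tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:]))
    return (t.chrom, t.strand, juncs)


# ---------------------------------------------------------------------------
# detection


def _truncate_exons(exons: tuple[GenomicInterval, ...], target: int = 150):
    """Trim an exon chain to < 200 nt total (degraded-fragment mimic)."""
    out, total = [], 0
    for e in exons:
        if total + len(e) >= 200:
            clip = min(len(e), max(1, target - total))
            out.append(GenomicInterval(e.chrom, e.start, e.start + clip, e.strand))
            break
        out.append(e)
        total += len(e)
    return tuple(out)


def _detect_from_counts(
    panel: ReferencePanel,
    counts: np.ndarray,
    depth: int,
    config: SimulationConfig,
    seed: int,
    sample_id: str,
) -> SimulatedSample:
    """Apply the detection rules to a per-transcript read-count pool."""
    arrays, latents = _panel_state(panel, seed, config.detection_correlation)
    k = config.junction_detect_threshold
    m = config.transcript_detect_threshold

    counts = np.asarray(counts, dtype=np.int64)
    p_feat = np.minimum(1.0, config.anchor_window / arrays.lengths)
    # marginal P(feature support >= k | n reads); monotone in n
    sf = binom.sf(k - 1, counts, p_feat)
    detected = latents.u < sf[arrays.feature_tidx]

    mangled_unstranded = latents.mangle < config.unstranded_fraction
    mangled_truncated = (~mangled_unstranded) & (
        latents.mangle < config.unstranded_fraction + config.truncate_fraction
    )

    meta = SampleMeta(
        sample_id=sample_id,
        group_label="simulated",
        total_reads=int(depth),
        mapped_reads=int(depth * config.mapped_fraction),
        assigned_reads=int(depth * config.mapped_fraction * config.assigned_fraction),
    )
    asm = Assembly(meta=meta)
    truth: dict[str, str] = {}
    full_ids: list[str] = []

    nz = np.nonzero(counts)[0]
    for i in nz:
        t = panel.transcripts[i]
        n_t = int(counts[i])
        off, nj = arrays.offsets[i], arrays.n_junctions[i]
        feat = detected[off: off + arrays.n_features[i]]
        junctions_ok = bool(feat[:nj].all())  # vacuous for single-exon
        exon_det = feat[nj:]
        if nj == 0:
            full = bool(exon_det[0]) and n_t >= m
        else:
            full = junctions_ok and n_t >= m
        cpm = 1e6 * n_t / depth if depth else float(n_t)
        if full:
            qid = f"{t.transcript_id}.f"
            exons = t.exons
            full_ids.append(t.transcript_id)
        elif exon_det.any():
            qid = f"{t.transcript_id}.p"
            exons = tuple(e for e, d in zip(t.exons, exon_det) if d)
        else:
            continue
        strand = t.strand
        if mangled_unstranded[i]:
            strand = UNSTRANDED
        elif mangled_truncated[i]:
            exons = _truncate_exons(exons)
        exons = tuple(
            GenomicInterval(e.chrom, e.start, e.end, strand) for e in exons
        ) if strand != t.strand else exons
        asm.add(
            TranscriptRecord(
                transcript_id=qid,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=strand,
                exons=exons,
                coding_class=t.coding_class,
                annotation_status=t.annotation_status,
                te_containing=t.te_containing,
                expression=cpm,
            )
        )
        truth[qid] = t.transcript_id

    _add_noise(panel, arrays, asm, truth, depth, config, seed, sample_id)
    return SimulatedSample(
        assembly=asm,
        truth_map=truth,
        depth=int(depth),
        read_counts=counts,
        panel=panel,
        seed=seed,
        sample_id=sample_id,
        fully_assembled=frozenset(full_ids),
    )


def _add_noise(panel, arrays, asm, truth, depth, config, seed, sample_id):
    if config.noise_rate == 0 or depth == 0:
        return
    rng0 = substream(seed, sample_id, "noise")
    n_noise = int(rng0.poisson(config.noise_rate * depth / 1e6))
    chroms = sorted(panel.genome)
    for j in range(n_noise):
        rng = substream(seed, sample_id, "noise", j)
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max(1, panel.genome[chrom] - 100_000)))
        n_exons = 1 + int(rng.poisson(1.5))
        exon_lens = np.maximum(
            30, np.round(rng.lognormal(math.log(200.0), 0.6, n_exons))
        ).astype(int)
        intron_lens = np.maximum(
            60, np.round(rng.lognormal(math.log(800.0), 0.6, max(n_exons - 1, 1)))
        ).astype(int)
        strand = "+" if rng.uniform() < 0.5 else "-"
        cls = CODING if rng.uniform() < config.noise_coding_prob else NONCODING
        reads = 1 + int(rng.poisson(1.0))
        while True:
            pos, exons = start, []
            for e in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[e]), strand)
                )
                pos += int(exon_lens[e])
                if e < n_exons - 1:
                    pos += int(intron_lens[e])
            rec = TranscriptRecord(
                transcript_id=f"noise_{sample_id}_{j}",
                gene_id=f"noise_gene_{sample_id}_{j}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                coding_class=cls,
                annotation_status=NOVEL,
                expression=1e6 * reads / depth,
            )
            if _chain_key(rec) not in arrays.chains:
                break
            start += 1009  # vanishingly rare collision with a panel chain
        asm.add(rec)
        truth[rec.transcript_id] = NOISE


def simulate_assembly(
    panel: ReferencePanel,
    depth: int,
    config: SimulationConfig,
    seed: int,
    sample_id: str = "sample",
) -> SimulatedSample:
    """Simulate one assembly at ``depth`` read pairs."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    n = len(panel)
    if depth == 0 or n == 0:
        return SimulatedSample(
            assembly=Assembly(meta=SampleMeta(sample_id=sample_id)),
            truth_map={},
            depth=0,
            read_counts=np.zeros(n, dtype=np.int64),
            panel=panel,
            seed=seed,
            sample_id=sample_id,
        )
    arrays, _ = _panel_state(panel, seed, config.detection_correlation)
    p = arrays.weights / arrays.weights.sum()
    counts = substream(seed, sample_id, "counts").multinomial(int(depth), p)
    return _detect_from_counts(panel, counts, int(depth), config, seed, sample_id)


def simulate_depth_series(
    panel: ReferencePanel,
    depths: Sequence[int],
    replicates: Sequence[int] | int,
    config: SimulationConfig,
    seed: int,
) -> list[SimulatedSample]:
    """Independent samples per (depth, replicate).

    ``replicates`` may be a single count or one count per depth, mirroring
    designs such as 20/10/4/2/1 replicates at increasing depths.
    """
    if not len(depths):
        raise ValueError("depths must be non-empty")
    if isinstance(replicates, int):
        replicates = [replicates] * len(depths)
    if len(replicates) != len(depths):
        raise ValueError("replicates must match depths in length")
    samples = []
    for d, r in zip(depths, replicates):
        for rep in range(r):
            samples.append(
                simulate_assembly(panel, d, config, seed, sample_id=f"d{d}_r{rep}")
            )
    return samples


def partition_subsample(
    sample: SimulatedSample,
    fractions: Sequence[float],
    config: SimulationConfig,
    seed: int,
) -> list[SimulatedSample]:
    """Subsample the read pool without replacement, one output per fraction.

    When the fractions sum to 1 (e.g. four times 25%) the outputs partition
    the pool disjointly. Detection rules are re-applied per subsample.
    """
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    if sum(fractions) > 1 + 1e-9:
        raise ValueError(
            f"fractions sum to {sum(fractions):.3f} > 1; cannot sample disjointly"
        )
    if fractions == [1.0]:
        return [replace(sample)]
    total = int(sample.read_counts.sum())
    remaining = sample.read_counts.copy()
    exact_partition = abs(sum(fractions) - 1.0) < 1e-9
    out = []
    for i, f in enumerate(fractions):
        if exact_partition and i == len(fractions) - 1:
            take = remaining.copy()
        else:
            size = min(int(round(f * total)), int(remaining.sum()))
            rng = substream(seed, "partition", sample.sample_id, i)
            take = rng.multivariate_hypergeometric(remaining, size)
        remaining = remaining - take
        out.append(
            _detect_from_counts(
                sample.panel,
                take,
                int(take.sum()),
                config,
                sample.seed,
                sample_id=f"{sample.sample_id}/sub{i}_{f:g}",
            )
        )
    return out


def merge_samples(
    samples: Sequence[SimulatedSample], config: SimulationConfig
) -> SimulatedSample:
    """Pool read sets and re-apply detection at the combined depth."""
    if not samples:
        raise ValueError("nothing to merge")
    panel = samples[0].panel
    if any(s.panel.uid != panel.uid for s in samples):
        raise ValueError("samples must share one ReferencePanel")
    if len(samples) == 1:
        return replace(samples[0])
    counts = np.sum([s.read_counts for s in samples], axis=0)
    depth = int(sum(s.depth for s in samples))
    sample_id = "merge(" + "+".join(s.sample_id for s in samples) + ")"
    return _detect_from_counts(
        panel, counts, depth, config, samples[0].seed, sample_id
    )


def generate_cell_matrix(
    panel: ReferencePanel,
    n_cells: int,
    seed: int,
    tag_log_mean: float = math.log(5000.0),
    tag_log_sd: float = 0.5,
    dropout_max: float = 0.9,
    dropout_scale: float = 2.0,
    transcript_ids: Optional[Sequence[str]] = None,
):
    """Sparse 3'-biased single-cell counts over the panel's transcripts.

    Per cell, the tag total is log-normal; counts are multinomial on
    ``expression x length`` after an extra per-(cell, transcript) dropout
    whose probability ``dropout_max * exp(-expression / dropout_scale)``
    decreases with expression. ``transcript_ids`` restricts quantification to
    a guiding transcript set. Deterministic given ``seed``.
    """
    from .sc_detection import CellMatrix

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    records = panel.transcripts
    if transcript_ids is not None:
        wanted = set(transcript_ids)
        records = [t for t in records if t.transcript_id in wanted]
    tids = [t.transcript_id for t in records]
    expr = np.array([t.expression for t in records])
    weights = np.array([t.expression * t.length for t in records], dtype=float)
    p_drop = dropout_max * np.exp(-expr / dropout_scale)
    counts = np.zeros((len(records), n_cells), dtype=np.int64)
    for c in range(n_cells):
        rng = substream(seed, "cell", c)
        tag_total = int(round(rng.lognormal(tag_log_mean, tag_log_sd)))
        dropped = rng.uniform(size=len(records)) < p_drop
        w = np.where(dropped, 0.0, weights)
        if w.sum() > 0 and tag_total > 0:
            counts[:, c] = rng.multinomial(tag_total, w / w.sum())
    classes = {t.transcript_id: t.coding_class for t in records}
    return CellMatrix(
        counts=counts, transcript_ids=tids,
        barcodes=[f"cell_{c:04d}" for c in range(n_cells)],
        classes=classes,
    )
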