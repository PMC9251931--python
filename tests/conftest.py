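import numpy as np
import pytest

from txdepth.types import (
    Assembly,
    GenomicInterval,
    SampleMeta,
    TranscriptRecord,
)


def make_transcript(
    tid,
    exons,
    chrom="chr1",
    strand="+",
    gene=None,
    coding_class="unknown",
    status="unknown",
    expression=0.0,
    te=None,
):
    """exons: list of (start, end) pairs."""
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gene or f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        coding_class=coding_class,
        annotation_status=status,
        expression=expression,
        te_containing=te,
    )


def make_assembly(transcripts, sample_id="test"):
    return Assembly.from_transcripts(transcripts, SampleMeta(sample_id=sample_id))


@pytest.fixture
def four_exon_ref():
    return make_transcript(
        "ref1", [(0, 100), (200, 300), (400, 500), (600, 700)], coding_class="coding"
    )


def random_instance(rng: np.random.Generator, n_max: int = 50):
    """A random (query, reference) pair of small assemblies that share
    structure: exact copies, truncations, isoform variants, single-exon
    overlaps and unrelated noise."""
    chroms = ["chrA", "chrB"]
    n_ref = int(rng.integers(3, n_max + 1))
    refs = []
    for i in range(n_ref):
        chrom = chroms[int(rng.integers(2))]
        strand = "+" if rng.uniform() < 0.5 else "-"
        n_ex = int(rng.integers(1, 6))
        pos = int(rng.integers(0, 5000))
        exons = []
        for _ in range(n_ex):
            ln = int(rng.integers(50, 300))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(60, 400))
        refs.append(
            make_transcript(
                f"r{i:03d}",
                exons,
                chrom=chrom,
                strand=strand,
                coding_class="coding" if rng.uniform() < 0.6 else "noncoding",
            )
        )
    queries = []
    qn = 0
    for ref in refs:
        u = rng.uniform()
        cls = "coding" if rng.uniform() < 0.6 else "noncoding"
        if u < 0.35:  # exact copy (maybe with jittered terminal boundaries)
            exons = [(e.start, e.end) for e in ref.exons]
            if rng.uniform() < 0.5:
                s0, e0 = exons[0]
                exons[0] = (max(0, s0 - int(rng.integers(0, 30))), e0)
            queries.append(
                make_transcript(
                    f"q{qn:03d}", exons, chrom=ref.chrom, strand=ref.strand,
                    coding_class=cls,
                )
            )
            qn += 1
        elif u < 0.55 and ref.n_exons >= 3:  # truncation: prefix of exons
            k = int(rng.integers(2, ref.n_exons))
            queries.append(
                make_transcript(
                    f"q{qn:03d}",
                    [(e.start, e.end) for e in ref.exons[:k]],
                    chrom=ref.chrom,
                    strand=ref.strand,
                    coding_class=cls,
                )
            )
            qn += 1
        elif u < 0.7 and ref.n_exons >= 2:  # isoform: shift one junction
            exons = [[e.start, e.end] for e in ref.exons]
            j = int(rng.integers(0, len(exons) - 1))
            exons[j][1] += int(rng.integers(1, 40))
            queries.append(
                make_transcript(
                    f"q{qn:03d}", [tuple(e) for e in exons],
                    chrom=ref.chrom, strand=ref.strand, coding_class=cls,
                )
            )
            qn += 1
        elif u < 0.8 and ref.n_exons == 1:  # overlapping single exon
            s, e = ref.exons[0].start, ref.exons[0].end
            d = int(rng.integers(0, max(2, (e - s) // 20)))
            queries.append(
                make_transcript(
                    f"q{qn:03d}", [(s + d, e)], chrom=ref.chrom,
                    strand=ref.strand, coding_class=cls,
                )
            )
            qn += 1
    n_noise = int(rng.integers(1, 6))
    for _ in range(n_noise):
        chrom = chroms[int(rng.integers(2))]
        strand = "+" if rng.uniform() < 0.5 else "-"
        pos = int(rng.integers(50_000, 90_000))
        n_ex = int(rng.integers(1, 4))
        exons = []
        for _ in range(n_ex):
            ln = int(rng.integers(50, 300))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(60, 400))
        queries.append(
            make_transcript(
                f"q{qn:03d}", exons, chrom=chrom, strand=strand,
                coding_class="coding" if rng.uniform() < 0.2 else "noncoding",
            )
        )
        qn += 1
    return make_assembly(queries, "query"), make_assembly(refs, "reference")
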