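"""Core data model: genomic intervals, transcripts, assemblies.

Coordinates are 0-based half-open everywhere inside the package; format
readers/writers convert at the boundary (GTF is 1-based inclusive, BED is
already 0-based half-open). Interval length is always ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

UNSTRANDED = "."
STRANDS = ("+", "-", UNSTRANDED)

CODING = "coding"
NONCODING = "noncoding"
UNKNOWN = "unknown"
CODING_CLASSES = (CODING, NONCODING, UNKNOWN)

ANNOTATED = "annotated"
VARIANT = "variant"
NOVEL = "novel"
ANNOTATION_STATUSES = (ANNOTATED, VARIANT, NOVEL, UNKNOWN)


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptRecord:
    """One transcript: strand + ordered exons + class/annotation attributes.

    ``exons`` are sorted by start and pairwise non-overlapping, all on
    ``chrom``. ``expression`` is an abundance in arbitrary non-negative units
    (the simulator uses CPM for assembled transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    coding_class: str = UNKNOWN
    annotation_status: str = UNKNOWN
    te_containing: Optional[bool] = None
    expression: float = 0.0
    recurrence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.coding_class not in CODING_CLASSES:
            raise ValueError(f"bad coding_class {self.coding_class!r}")
        if self.annotation_status not in ANNOTATION_STATUSES:
            raise ValueError(f"bad annotation_status {self.annotation_status!r}")
        if self.expression < 0:
            raise ValueError("expression must be non-negative")
        exons = tuple(self.exons)
        if not exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"exon on {e.chrom} but transcript {self.transcript_id} "
                    f"on {self.chrom}"
                )
        if list(exons) != sorted(exons, key=lambda e: e.start):
            raise ValueError(f"exons of {self.transcript_id} not sorted by start")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def with_(self, **changes) -> "TranscriptRecord":
        return replace(self, **changes)


@dataclass
class SampleMeta:
    """Read-depth bookkeeping for one sample.

    The three depth levels are total reads, reads mapped to the genome, and
    reads assigned to a transcript.
    """

    sample_id: str
    group_label: str = ""
    total_reads: int = 0
    mapped_reads: int = 0
    assigned_reads: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.assigned_reads <= self.mapped_reads <= self.total_reads):
            raise ValueError(
                "require 0 <= assigned <= mapped <= total, got "
                f"{self.assigned_reads}/{self.mapped_reads}/{self.total_reads}"
            )


@dataclass
class Assembly:
    """A set of transcripts from one sample, keyed by transcript_id."""

    meta: SampleMeta
    transcripts: dict[str, TranscriptRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, t in self.transcripts.items():
            if tid != t.transcript_id:
                raise ValueError(f"key {tid!r} != transcript_id {t.transcript_id!r}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def add(self, t: TranscriptRecord) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self.transcripts[t.transcript_id] = t

    @classmethod
    def from_transcripts(
        cls, transcripts: Iterable[TranscriptRecord], meta: SampleMeta | None = None
    ) -> "Assembly":
        asm = cls(meta=meta or SampleMeta(sample_id="assembly"))
        for t in transcripts:
            asm.add(t)
        return asm

    def class_counts(self) -> dict[str, int]:
        counts = {CODING: 0, NONCODING: 0, UNKNOWN: 0}
        for t in self:
            counts[t.coding_class] += 1
        return counts
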