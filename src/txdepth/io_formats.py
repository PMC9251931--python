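"""Readers/writers for GTF, BED, class tables and count matrices.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention at this boundary; BED is already 0-based half-open and
passes through. Attribute parsing accepts both the quoted GENCODE dialect
(``key "value";``) and unquoted ``key value;`` pairs; the writer emits
GENCODE style. All writers emit a deterministic ordering (chrom, start,
transcript_id).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    ANNOTATION_STATUSES,
    CODING,
    CODING_CLASSES,
    NONCODING,
    UNKNOWN,
    UNSTRANDED,
    Assembly,
    GenomicInterval,
    SampleMeta,
    TranscriptRecord,
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


_ATTR_RE = re.compile(r'\s*(\w+)\s+(?:"([^"]*)"|([^;"\s]+))\s*;?')


def _parse_attributes(field: str) -> dict[str, str]:
    return {
        m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
        for m in _ATTR_RE.finditer(field)
    }


def read_gtf(path: str | Path, attribute_map: Mapping[str, str] | None = None) -> Assembly:
    """Read exon features of a GTF file into an :class:`Assembly`.

    ``attribute_map`` renames attribute keys on the fly (e.g.
    ``{"ref_gene_id": "gene_id"}``). Strand ``.`` maps to unstranded; the
    optional ``coding_class`` / ``annotation_status`` / ``te_containing`` /
    ``expression`` attributes populate the corresponding record fields and
    default to unknown.
    """
    path = Path(path)
    attribute_map = dict(attribute_map or {})
    exons: dict[str, list[GenomicInterval]] = {}
    info: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if end1 < start1:
                raise ParseError(f"{path.name}:{lineno}: end < start")
            attrs = _parse_attributes(attrs_s)
            for old, new in attribute_map.items():
                if old in attrs:
                    attrs[new] = attrs.pop(old)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(f"{path.name}:{lineno}: exon without transcript_id")
            if strand not in ("+", "-"):
                strand = UNSTRANDED
            # GTF 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons.setdefault(tid, []).append(iv)
            meta = info.setdefault(tid, {"strand": strand, "chrom": chrom})
            if meta["chrom"] != chrom:
                raise ParseError(
                    f"{path.name}:{lineno}: transcript {tid} spans multiple "
                    f"chromosomes ({meta['chrom']} and {chrom})"
                )
            for key in ("gene_id", "coding_class", "annotation_status",
                        "te_containing", "expression"):
                if key in attrs:
                    meta[key] = attrs[key]

    asm = Assembly(meta=SampleMeta(sample_id=path.stem))
    for tid in sorted(exons):
        ivs = sorted(exons[tid], key=lambda e: e.start)
        meta = info[tid]
        cls = meta.get("coding_class", UNKNOWN)
        if cls not in CODING_CLASSES:
            raise ParseError(f"{path.name}: bad coding_class {cls!r} for {tid}")
        status = meta.get("annotation_status", UNKNOWN)
        if status not in ANNOTATION_STATUSES:
            raise ParseError(f"{path.name}: bad annotation_status {status!r} for {tid}")
        te_raw = meta.get("te_containing")
        te = None if te_raw is None else te_raw.lower() == "true"
        strand = meta["strand"]
        asm.add(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=meta.get("gene_id", tid),
                chrom=meta["chrom"],
                strand=strand,
                exons=tuple(
                    GenomicInterval(e.chrom, e.start, e.end, strand) for e in ivs
                ),
                coding_class=cls,
                annotation_status=status,
                te_containing=te,
                expression=float(meta.get("expression", 0.0)),
            )
        )
    return asm


def write_gtf(assembly: Assembly, path: str | Path) -> None:
    """Write transcript and exon features, converting back to 1-based GTF."""
    path = Path(path)
    order = sorted(assembly, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in order:
            attrs = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"']
            if t.coding_class != UNKNOWN:
                attrs.append(f'coding_class "{t.coding_class}"')
            if t.annotation_status != UNKNOWN:
                attrs.append(f'annotation_status "{t.annotation_status}"')
            if t.te_containing is not None:
                attrs.append(f'te_containing "{t.te_containing}"')
            if t.expression:
                attrs.append(f'expression "{t.expression:.6g}"')
            attr_s = "; ".join(attrs) + ";"
            fh.write(
                f"{t.chrom}\ttxdepth\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attr_s}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\ttxdepth\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attr_s}\n"
                )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open; strand column honored if present)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            if end <= start:
                raise ParseError(f"{path.name}:{lineno}: end <= start")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else UNSTRANDED
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_class_table(path: str | Path) -> dict[str, str]:
    """Read a TSV of (transcript_id, class) with class in {coding, noncoding}.

    Stands in for a coding-potential caller's output. Duplicate ids with
    conflicting classes are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "class"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{Path(path).name}: need columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    bad = sorted(set(df["class"]) - {CODING, NONCODING})
    if bad:
        raise ParseError(f"{Path(path).name}: unknown class value(s) {bad}")
    out: dict[str, str] = {}
    for tid, cls in zip(df["transcript_id"], df["class"]):
        if tid in out and out[tid] != cls:
            raise ParseError(
                f"{Path(path).name}: conflicting classes for {tid!r}: "
                f"{out[tid]} vs {cls}"
            )
        out[tid] = cls
    return out


def apply_class_table(
    assembly: Assembly, table: Mapping[str, str], overwrite: bool = False
) -> Assembly:
    """Join class labels onto an assembly.

    By default only ``unknown`` classes are overwritten; with
    ``overwrite=True`` the table wins everywhere it has an entry.
    """
    out = Assembly(meta=assembly.meta)
    for t in assembly:
        cls = table.get(t.transcript_id)
        if cls is not None and (overwrite or t.coding_class == UNKNOWN):
            t = t.with_(coding_class=cls)
        out.add(t)
    return out


def write_class_table(assembly: Assembly, path: str | Path) -> None:
    rows = [
        {"transcript_id": t.transcript_id, "class": t.coding_class}
        for t in sorted(assembly, key=lambda t: t.transcript_id)
        if t.coding_class != UNKNOWN
    ]
    pd.DataFrame(rows, columns=["transcript_id", "class"]).to_csv(
        path, sep="\t", index=False
    )


def _validate_counts(values: np.ndarray, name: str) -> np.ndarray:
    if np.any(values < 0):
        raise ParseError(f"{name}: negative count")
    if not np.allclose(values, np.round(values)):
        raise ParseError(f"{name}: non-integer count")
    return np.asarray(np.round(values), dtype=np.int64)


def read_counts_matrix(path: str | Path):
    """Read a transcripts x cells count matrix into a :class:`CellMatrix`.

    Two encodings are accepted: a dense TSV whose first column is
    transcript_id and whose header row holds cell barcodes, or a MatrixMarket
    triplet ``*.mtx`` with sidecar files ``<stem>.rows.tsv`` (transcript ids)
    and ``<stem>.cols.tsv`` (barcodes).
    """
    from .sc_detection import CellMatrix

    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        counts = _validate_counts(np.asarray(mat, dtype=float), path.name)
        rows = (path.parent / (path.stem + ".rows.tsv")).read_text().split()
        cols = (path.parent / (path.stem + ".cols.tsv")).read_text().split()
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = _validate_counts(df.to_numpy(dtype=float), path.name)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
    if counts.shape != (len(rows), len(cols)):
        raise ParseError(f"{path.name}: matrix shape does not match sidecar names")
    return CellMatrix(counts=counts, transcript_ids=list(rows), barcodes=list(cols))


def write_counts_matrix(matrix, path: str | Path) -> None:
    """Write a CellMatrix as dense TSV (``.tsv``) or MatrixMarket (``.mtx``)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts))
        (path.parent / (path.stem + ".rows.tsv")).write_text(
            "\n".join(matrix.transcript_ids) + "\n"
        )
        (path.parent / (path.stem + ".cols.tsv")).write_text(
            "\n".join(matrix.barcodes) + "\n"
        )
    else:
        pd.DataFrame(
            matrix.counts, index=matrix.transcript_ids, columns=matrix.barcodes
        ).to_csv(path, sep="\t", index_label="transcript_id")
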