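"""Reference-based assembly evaluation.

Matching semantics: a reference transcript is *correctly assembled* when
some query transcript has an identical intron chain on the same strand
(exact junction coordinates; terminal exon outer boundaries are free). For
single-exon transcripts, which have no junctions, correctness falls back to
a same-strand single-exon query with reciprocal overlap of at least
``single_exon_overlap`` (default 0.9).

Splice completeness of a reference transcript is the percentage of its
junctions found in any same-chrom, same-strand query transcript. Exon
completeness is scored against the single best-matching query transcript
(most shared junctions; ties broken by shared exon boundaries, then by id;
an exact intron-chain match always wins): internal exons must match both
boundaries exactly, terminal exons only their splice-side boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    CODING,
    NONCODING,
    UNKNOWN,
    Assembly,
    GenomicInterval,
    SampleMeta,
    TranscriptRecord,
)

Junction = tuple[int, int]


def filter_assembly(
    assembly: Assembly, min_length: int = 200, require_strand: bool = True
) -> Assembly:
    """Discard transcripts with no inferred strand or shorter than ``min_length`` nt.

    The length threshold is on summed exon length and is inclusive: a
    transcript of exactly ``min_length`` nt is retained. The input is
    untouched.
    """
    out = Assembly(meta=assembly.meta)
    for t in assembly:
        if require_strand and t.strand not in ("+", "-"):
            continue
        if t.length < min_length:
            continue
        out.add(t)
    return out


def intron_chain(t: TranscriptRecord) -> tuple[str, str, tuple[Junction, ...]]:
    """(chrom, strand, ordered junctions); empty junction list if single-exon."""
    return (
        t.chrom,
        t.strand,
        tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:])),
    )


@dataclass
class MatchResult:
    reference_id: str
    exon_completeness: float
    splice_completeness: float
    correctly_assembled: bool
    best_query_id: Optional[str] = None


@dataclass
class EvalMetrics:
    """Sensitivity/precision per class and overall; ``None`` = undefined."""

    sensitivity: dict[str, Optional[float]] = field(default_factory=dict)
    precision: dict[str, Optional[float]] = field(default_factory=dict)
    n_reference: dict[str, int] = field(default_factory=dict)
    n_query: dict[str, int] = field(default_factory=dict)


def _reciprocal_overlap(a: TranscriptRecord, b: TranscriptRecord) -> float:
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(ov / len(a.exons[0]), ov / len(b.exons[0])) if ov else 0.0


class _QueryIndex:
    """Lookup structures over a query assembly, keyed by (chrom, strand)."""

    def __init__(self, query: Assembly):
        self.junctions: dict[tuple, set[Junction]] = {}
        self.junction_owners: dict[tuple, dict[Junction, list[str]]] = {}
        self.chains: dict[tuple, list[str]] = {}
        self.single_exon: dict[tuple, IntervalTree] = {}
        self.exon_sets: dict[str, set[tuple[int, int]]] = {}
        self.end_sets: dict[str, set[int]] = {}
        self.start_sets: dict[str, set[int]] = {}
        self.by_id = query.transcripts
        for t in query:
            key = (t.chrom, t.strand)
            chrom, _strand, juncs = intron_chain(t)
            self.exon_sets[t.transcript_id] = {(e.start, e.end) for e in t.exons}
            self.end_sets[t.transcript_id] = {e.end for e in t.exons}
            self.start_sets[t.transcript_id] = {e.start for e in t.exons}
            if juncs:
                self.chains.setdefault((chrom, t.strand, juncs), []).append(
                    t.transcript_id
                )
                owners = self.junction_owners.setdefault(key, {})
                jset = self.junctions.setdefault(key, set())
                for j in juncs:
                    jset.add(j)
                    owners.setdefault(j, []).append(t.transcript_id)
            else:
                self.single_exon.setdefault(key, IntervalTree()).addi(
                    t.start, t.end, t.transcript_id
                )

    def single_exon_matches(
        self, ref: TranscriptRecord, min_frac: float
    ) -> list[str]:
        tree = self.single_exon.get((ref.chrom, ref.strand))
        if tree is None:
            return []
        out = []
        for hit in tree.overlap(ref.start, ref.end):
            q = self.by_id[hit.data]
            if _reciprocal_overlap(ref, q) >= min_frac:
                out.append(hit.data)
        return sorted(out)


def _shared_boundaries(ref: TranscriptRecord, idx: _QueryIndex, qid: str) -> int:
    q_bounds = idx.start_sets[qid] | idx.end_sets[qid]
    n = 0
    for e in ref.exons:
        n += (e.start in q_bounds) + (e.end in q_bounds)
    return n


def _exon_completeness(ref: TranscriptRecord, idx: _QueryIndex, qid: str) -> float:
    exact = idx.exon_sets[qid]
    ends = idx.end_sets[qid]
    starts = idx.start_sets[qid]
    n = ref.n_exons
    recovered = 0
    for i, e in enumerate(ref.exons):
        if i == 0 and n > 1:
            recovered += e.end in ends
        elif i == n - 1 and n > 1:
            recovered += e.start in starts
        else:  # internal exon (or the only exon, handled by caller)
            recovered += (e.start, e.end) in exact
    return 100.0 * recovered / n


def match_assembly(
    query: Assembly,
    reference: Assembly,
    single_exon_overlap: float = 0.9,
) -> list[MatchResult]:
    """Score every reference transcript against a query assembly."""
    if len(reference) == 0:
        raise ValueError("empty reference: nothing to evaluate")
    idx = _QueryIndex(query)
    results = []
    for ref in sorted(reference, key=lambda t: t.transcript_id):
        chrom, strand, juncs = intron_chain(ref)
        key = (chrom, strand)
        if not juncs:
            hits = idx.single_exon_matches(ref, single_exon_overlap)
            correct = bool(hits)
            score = 100.0 if correct else 0.0
            results.append(
                MatchResult(
                    reference_id=ref.transcript_id,
                    exon_completeness=score,
                    splice_completeness=score,
                    correctly_assembled=correct,
                    best_query_id=hits[0] if hits else None,
                )
            )
            continue
        qjuncs = idx.junctions.get(key, set())
        shared = [j for j in juncs if j in qjuncs]
        splice = 100.0 * len(shared) / len(juncs)
        exact_ids = idx.chains.get((chrom, strand, juncs), [])
        correct = bool(exact_ids)
        if exact_ids:
            best = min(exact_ids)
        elif shared:
            owners = idx.junction_owners[key]
            tally: dict[str, int] = {}
            for j in shared:
                for qid in owners[j]:
                    tally[qid] = tally.get(qid, 0) + 1
            best = min(
                tally,
                key=lambda q: (-tally[q], -_shared_boundaries(ref, idx, q), q),
            )
        else:
            best = None
        exon = _exon_completeness(ref, idx, best) if best else 0.0
        results.append(
            MatchResult(
                reference_id=ref.transcript_id,
                exon_completeness=exon,
                splice_completeness=splice,
                correctly_assembled=correct,
                best_query_id=best,
            )
        )
    return results


# ---------------------------------------------------------------------------
# summaries


@dataclass
class CompletenessSummary:
    """Shares of reference transcripts at exactly 100%, exactly 0%, and between.

    ``table`` rows: (coding_class, feature, complete, missing, partial) in
    percent, plus SD columns when summarising several replicate result sets.
    """

    table: pd.DataFrame

    def row(self, coding_class: str, feature: str) -> pd.Series:
        t = self.table
        return t[(t.coding_class == coding_class) & (t.feature == feature)].iloc[0]


def _one_completeness(
    results: Sequence[MatchResult], classes: Mapping[str, str]
) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.reference_id not in classes:
            raise ValueError(f"missing class label for {r.reference_id!r}")
    for cls in (CODING, NONCODING):
        sub = [r for r in results if classes[r.reference_id] == cls]
        for feature in ("exon", "splice"):
            vals = np.array(
                [
                    r.exon_completeness if feature == "exon" else r.splice_completeness
                    for r in sub
                ]
            )
            n = len(vals)
            comp = 100.0 * np.sum(vals == 100.0) / n if n else np.nan
            miss = 100.0 * np.sum(vals == 0.0) / n if n else np.nan
            rows.append(
                {
                    "coding_class": cls,
                    "feature": feature,
                    "n": n,
                    "complete": comp,
                    "missing": miss,
                    "partial": 100.0 - comp - miss if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def completeness_table(
    results: Sequence[MatchResult] | Sequence[Sequence[MatchResult]],
    classes: Mapping[str, str],
) -> CompletenessSummary:
    """Exon/splice completeness shares per class.

    Given one result list, returns its shares. Given a list of result lists
    (replicate samples), returns means with SD columns (``complete_sd`` etc.),
    the layout used for replicate-averaged completeness reporting.
    """
    if results and isinstance(results[0], MatchResult):
        return CompletenessSummary(table=_one_completeness(results, classes))
    per_rep = [_one_completeness(r, classes) for r in results]
    stacked = pd.concat(per_rep)
    agg = stacked.groupby(["coding_class", "feature"], as_index=False).agg(
        n=("n", "mean"),
        complete=("complete", "mean"),
        complete_sd=("complete", lambda s: s.std(ddof=0)),
        missing=("missing", "mean"),
        missing_sd=("missing", lambda s: s.std(ddof=0)),
        partial=("partial", "mean"),
        partial_sd=("partial", lambda s: s.std(ddof=0)),
    )
    return CompletenessSummary(table=agg)


def _per_class_fraction(flags: dict[str, bool], classes: Mapping[str, str]):
    out: dict[str, Optional[float]] = {}
    counts: dict[str, int] = {}
    groups: dict[str, list[bool]] = {CODING: [], NONCODING: [], "overall": []}
    for tid, ok in flags.items():
        cls = classes.get(tid, UNKNOWN)
        if cls in (CODING, NONCODING):
            groups[cls].append(ok)
        groups["overall"].append(ok)
    for g, vals in groups.items():
        counts[g] = len(vals)
        out[g] = (sum(vals) / len(vals)) if vals else None
    return out, counts


def sensitivity(
    results: Sequence[MatchResult], classes: Mapping[str, str]
) -> EvalMetrics:
    """Fraction of reference transcripts correctly assembled, per class."""
    flags = {r.reference_id: r.correctly_assembled for r in results}
    sens, counts = _per_class_fraction(flags, classes)
    return EvalMetrics(sensitivity=sens, n_reference=counts)


def precision(
    query: Assembly,
    reference: Assembly,
    classes: Mapping[str, str] | None = None,
    single_exon_overlap: float = 0.9,
) -> EvalMetrics:
    """Fraction of query transcripts matching some reference transcript.

    A query transcript's class is taken from its own label (or from
    ``classes`` when given). Each query transcript counts at most once even
    if it matches several reference transcripts. Zero denominators yield
    ``None`` (undefined), never 0.
    """
    ref_idx = _QueryIndex(reference)
    flags: dict[str, bool] = {}
    qclasses: dict[str, str] = {}
    for q in query:
        chrom, strand, juncs = intron_chain(q)
        if juncs:
            ok = (chrom, strand, juncs) in ref_idx.chains
        else:
            ok = bool(ref_idx.single_exon_matches(q, single_exon_overlap))
        flags[q.transcript_id] = ok
        qclasses[q.transcript_id] = (
            classes.get(q.transcript_id, q.coding_class) if classes else q.coding_class
        )
    prec, counts = _per_class_fraction(flags, qclasses)
    return EvalMetrics(precision=prec, n_query=counts)


def classify_annotation_status(
    query: Assembly,
    annotation: Assembly,
    single_exon_overlap: float = 0.9,
) -> dict[str, str]:
    """annotated = chain match; novel = no exonic overlap with any annotated
    exon on either strand; variant = exon overlap but different structure."""
    idx = _QueryIndex(annotation)
    exon_trees: dict[str, IntervalTree] = {}
    for t in annotation:
        for e in t.exons:
            exon_trees.setdefault(t.chrom, IntervalTree()).addi(e.start, e.end)
    out = {}
    for q in query:
        chrom, strand, juncs = intron_chain(q)
        if juncs:
            matched = (chrom, strand, juncs) in idx.chains
        else:
            matched = bool(idx.single_exon_matches(q, single_exon_overlap))
        if matched:
            out[q.transcript_id] = "annotated"
            continue
        tree = exon_trees.get(q.chrom)
        overlaps = tree is not None and any(
            tree.overlap(e.start, e.end) for e in q.exons
        )
        out[q.transcript_id] = "variant" if overlaps else "novel"
    return out


def annotate_te_overlap(
    assembly: Assembly,
    te_intervals: Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> Assembly:
    """Set ``te_containing`` by exonic, strand-agnostic TE overlap.

    A transcript is TE-containing iff any exon overlaps any TE interval by
    at least ``min_overlap`` nt. Output is independent of input ordering.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in te_intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = Assembly(meta=assembly.meta)
    for t in assembly:
        tree = trees.get(t.chrom)
        te = False
        if tree is not None:
            for e in t.exons:
                for hit in tree.overlap(e.start, e.end):
                    if min(e.end, hit.end) - max(e.start, hit.begin) >= min_overlap:
                        te = True
                        break
                if te:
                    break
        out.add(t.with_(te_containing=te))
    return out


def recurrence_filter(
    assemblies: Sequence[Assembly],
    min_samples: int,
    single_exon_overlap: float = 0.9,
) -> Assembly:
    """Transcripts whose identical assembly occurs in >= ``min_samples`` samples.

    Multi-exon transcripts are keyed by intron chain; single-exon transcripts
    are clustered by same-strand reciprocal overlap, with the longest member
    as cluster representative. Each output transcript carries its recurrence
    count in ``recurrence``. Presence is counted per assembly, not per copy.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not assemblies:
        raise ValueError("need at least one assembly")
    chain_samples: dict[tuple, set[int]] = {}
    chain_rep: dict[tuple, TranscriptRecord] = {}
    singles: list[tuple[int, TranscriptRecord]] = []
    for si, asm in enumerate(assemblies):
        for t in asm:
            chrom, strand, juncs = intron_chain(t)
            if juncs:
                key = (chrom, strand, juncs)
                chain_samples.setdefault(key, set()).add(si)
                rep = chain_rep.get(key)
                if rep is None or (t.length, rep.transcript_id) > (
                    rep.length, t.transcript_id
                ):
                    chain_rep[key] = t
            else:
                singles.append((si, t))

    out: list[TranscriptRecord] = []
    for key, samples in chain_samples.items():
        if len(samples) >= min_samples:
            out.append(chain_rep[key].with_(recurrence=len(samples)))

    # greedy single-exon clustering against the longest representative
    singles.sort(key=lambda p: (-p[1].length, p[1].transcript_id))
    clusters: list[tuple[TranscriptRecord, set[int]]] = []
    for si, t in singles:
        placed = False
        for rep, members in clusters:
            if (
                rep.chrom == t.chrom
                and rep.strand == t.strand
                and _reciprocal_overlap(rep, t) >= single_exon_overlap
            ):
                members.add(si)
                placed = True
                break
        if not placed:
            clusters.append((t, {si}))
    for rep, members in clusters:
        if len(members) >= min_samples:
            out.append(rep.with_(recurrence=len(members)))

    result = Assembly(meta=SampleMeta(sample_id=f"recurrent_ge{min_samples}"))
    used: dict[str, int] = {}
    for t in sorted(out, key=lambda t: (t.chrom, t.start, t.transcript_id)):
        tid = t.transcript_id
        if tid in result.transcripts:  # same id can represent several clusters
            used[tid] = used.get(tid, 0) + 1
            t = t.with_(transcript_id=f"{tid}#{used[tid]}")
        result.add(t)
    return result


def eval_metrics_frame(metrics: EvalMetrics) -> pd.DataFrame:
    rows = []
    for g in sorted(set(metrics.sensitivity) | set(metrics.precision)):
        rows.append(
            {
                "stratum": g,
                "sensitivity": metrics.sensitivity.get(g),
                "precision": metrics.precision.get(g),
                "n_reference": metrics.n_reference.get(g),
                "n_query": metrics.n_query.get(g),
            }
        )
    return pd.DataFrame(rows)
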