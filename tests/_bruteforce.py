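"""Independent brute-force reimplementations used as oracles.

Everything here works by explicit per-pair set operations over tiny
instances, with no index structures, so it stays independent of the
package's implementation paths.
"""

from __future__ import annotations

import numpy as np

from txdepth.types import Assembly, TranscriptRecord


def chain_of(t: TranscriptRecord):
    return (
        t.chrom,
        t.strand,
        tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:])),
    )


def reciprocal_overlap(a: TranscriptRecord, b: TranscriptRecord) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    if ov == 0:
        return 0.0
    return min(ov / len(a.exons[0]), ov / len(b.exons[0]))


def single_exon_match(ref, q, min_frac) -> bool:
    return (
        q.n_exons == 1
        and ref.n_exons == 1
        and q.chrom == ref.chrom
        and q.strand == ref.strand
        and reciprocal_overlap(ref, q) >= min_frac
    )


def bf_match(query: Assembly, reference: Assembly, min_frac: float = 0.9):
    """Per-reference (exon%, splice%, correct, best_query_id)."""
    out = {}
    queries = sorted(query, key=lambda t: t.transcript_id)
    for ref in reference:
        _, _, rj = chain_of(ref)
        if not rj:  # single exon
            hits = sorted(
                q.transcript_id for q in queries if single_exon_match(ref, q, min_frac)
            )
            score = 100.0 if hits else 0.0
            out[ref.transcript_id] = (
                score, score, bool(hits), hits[0] if hits else None
            )
            continue
        same = [
            q for q in queries if q.chrom == ref.chrom and q.strand == ref.strand
        ]
        all_j = set()
        for q in same:
            all_j |= set(chain_of(q)[2])
        splice = 100.0 * sum(j in all_j for j in rj) / len(rj)
        exact = sorted(
            q.transcript_id for q in same if chain_of(q)[2] == rj
        )
        # best query: exact chain wins; else most shared junctions, then most
        # shared exon boundaries, then lexicographic id
        best = None
        if exact:
            best = exact[0]
        else:
            scored = []
            for q in same:
                shared = len(set(chain_of(q)[2]) & set(rj))
                if shared == 0:
                    continue
                bounds = {e.start for e in q.exons} | {e.end for e in q.exons}
                nb = sum(
                    (e.start in bounds) + (e.end in bounds) for e in ref.exons
                )
                scored.append((-shared, -nb, q.transcript_id))
            if scored:
                best = min(scored)[2]
        exon = 0.0
        if best is not None:
            q = query.transcripts[best]
            q_exact = {(e.start, e.end) for e in q.exons}
            q_starts = {e.start for e in q.exons}
            q_ends = {e.end for e in q.exons}
            rec = 0
            n = ref.n_exons
            for i, e in enumerate(ref.exons):
                if i == 0:
                    rec += e.end in q_ends
                elif i == n - 1:
                    rec += e.start in q_starts
                else:
                    rec += (e.start, e.end) in q_exact
            exon = 100.0 * rec / n
        out[ref.transcript_id] = (exon, splice, bool(exact), best)
    return out


def bf_sensitivity(matches, classes):
    out = {}
    for cls in ("coding", "noncoding", "overall"):
        flags = [
            correct
            for rid, (_, _, correct, _) in matches.items()
            if cls == "overall" or classes[rid] == cls
        ]
        out[cls] = sum(flags) / len(flags) if flags else None
    return out


def bf_precision(query: Assembly, reference: Assembly, min_frac: float = 0.9):
    ref_chains = {chain_of(r) for r in reference if r.n_exons > 1}
    flags = {}
    for q in query:
        if q.n_exons > 1:
            ok = chain_of(q) in ref_chains
        else:
            ok = any(single_exon_match(q, r, min_frac) for r in reference)
        flags[q.transcript_id] = ok
    out = {}
    for cls in ("coding", "noncoding", "overall"):
        vals = [
            ok
            for tid, ok in flags.items()
            if cls == "overall" or query.transcripts[tid].coding_class == cls
        ]
        out[cls] = sum(vals) / len(vals) if vals else None
    return out


def bf_completeness(matches, classes):
    out = {}
    for cls in ("coding", "noncoding"):
        for fi, feature in ((0, "exon"), (1, "splice")):
            vals = [
                matches[rid][fi] for rid in matches if classes[rid] == cls
            ]
            n = len(vals)
            if n == 0:
                out[(cls, feature)] = (np.nan, np.nan, np.nan)
                continue
            comp = 100.0 * sum(v == 100.0 for v in vals) / n
            miss = 100.0 * sum(v == 0.0 for v in vals) / n
            out[(cls, feature)] = (comp, miss, 100.0 - comp - miss)
    return out


def bf_classify(query: Assembly, annotation: Assembly, min_frac: float = 0.9):
    ann_chains = {chain_of(a) for a in annotation if a.n_exons > 1}
    out = {}
    for q in query:
        if q.n_exons > 1:
            matched = chain_of(q) in ann_chains
        else:
            matched = any(single_exon_match(q, a, min_frac) for a in annotation)
        if matched:
            out[q.transcript_id] = "annotated"
            continue
        overlaps = any(
            e.chrom == ae.chrom and min(e.end, ae.end) > max(e.start, ae.start)
            for q_e in [q]
            for e in q_e.exons
            for a in annotation
            for ae in a.exons
        )
        out[q.transcript_id] = "variant" if overlaps else "novel"
    return out


def bf_recurrence_counts(assemblies, min_frac: float = 0.9):
    """Multi-exon chains -> number of assemblies containing them (the
    single-exon side is checked separately in dedicated tests)."""
    tally = {}
    for asm in assemblies:
        seen = {chain_of(t) for t in asm if t.n_exons > 1}
        for c in seen:
            tally[c] = tally.get(c, 0) + 1
    return tally


def bf_cumulative(expressions, flags=None, classes=None):
    """Prefix-scan curves over an already-ranked list."""
    n = len(expressions)
    total = float(sum(expressions))
    cum_expr, cum_prec, cum_ratio = [], [], []
    s = 0.0
    m = 0
    nc = 0
    ncod = 0
    for i in range(n):
        s += expressions[i]
        cum_expr.append(100.0 * s / total)
        if flags is not None:
            m += bool(flags[i])
            cum_prec.append(m / (i + 1))
        if classes is not None:
            ncod += classes[i] == "coding"
            nc += classes[i] == "noncoding"
            cum_ratio.append(ncod / nc if nc else np.nan)
    return cum_expr, cum_prec, cum_ratio
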