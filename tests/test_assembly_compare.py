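import numpy as np
import pytest

from _bruteforce import bf_match, bf_recurrence_counts
from conftest import make_assembly, make_transcript, random_instance
from txdepth.assembly_compare import (
    annotate_te_overlap,
    classify_annotation_status,
    completeness_table,
    filter_assembly,
    intron_chain,
    match_assembly,
    precision,
    recurrence_filter,
    sensitivity,
)
from txdepth.types import GenomicInterval


class TestFilterAssembly:
    @pytest.mark.parametrize(
        "length,strand,kept",
        [
            (199, "+", False),  # shorter than 200 nt -> discarded
            (200, "+", True),  # exactly 200 nt -> retained
            (10_000, ".", False),  # no inferred strand -> discarded
            (250, "-", True),
        ],
    )
    def test_length_and_strand_rules(self, length, strand, kept):
        asm = make_assembly([make_transcript("t", [(0, length)], strand=strand)])
        out = filter_assembly(asm)
        assert ("t" in out.transcripts) == kept

    def test_spliced_length_is_summed_exon_length(self):
        # two 100-nt exons span a large interval but total exactly 200
        asm = make_assembly([make_transcript("t", [(0, 100), (5000, 5100)])])
        assert "t" in filter_assembly(asm).transcripts

    def test_input_untouched_and_strand_optional(self):
        asm = make_assembly([make_transcript("t", [(0, 500)], strand=".")])
        out = filter_assembly(asm, require_strand=False)
        assert "t" in out.transcripts
        assert "t" in asm.transcripts


class TestIntronChain:
    def test_two_exons_one_junction(self):
        t = make_transcript("t", [(0, 100), (200, 300)])
        assert intron_chain(t) == ("chr1", "+", ((100, 200),))

    def test_single_exon_empty_chain(self):
        t = make_transcript("t", [(0, 100)])
        assert intron_chain(t)[2] == ()

    def test_four_exons_three_junctions(self, four_exon_ref):
        assert intron_chain(four_exon_ref)[2] == (
            (100, 200),
            (300, 400),
            (500, 600),
        )


class TestMatchAssembly:
    def test_self_match_identity(self, four_exon_ref):
        asm = make_assembly([four_exon_ref, make_transcript("s", [(900, 1200)])])
        for r in match_assembly(asm, asm):
            assert r.exon_completeness == 100.0
            assert r.splice_completeness == 100.0
            assert r.correctly_assembled

    def test_disjoint_chromosomes_all_zero(self, four_exon_ref):
        q = make_assembly([make_transcript("q", [(0, 100), (200, 300)], chrom="chr9")])
        (r,) = match_assembly(q, make_assembly([four_exon_ref]))
        assert (r.exon_completeness, r.splice_completeness) == (0.0, 0.0)
        assert not r.correctly_assembled

    def test_two_of_four_exons(self, four_exon_ref):
        """Query holding exons 1-2 only: exon completeness 50, splice 33.3."""
        q = make_assembly([make_transcript("q", [(0, 100), (200, 300)])])
        (r,) = match_assembly(q, make_assembly([four_exon_ref]))
        assert r.exon_completeness == 50.0
        assert r.splice_completeness == pytest.approx(100 / 3)
        assert not r.correctly_assembled
        assert r.best_query_id == "q"

    def test_terminal_boundaries_free(self, four_exon_ref):
        """Same intron chain with different outer ends is still correct."""
        q = make_assembly(
            [
                make_transcript(
                    "q", [(40, 100), (200, 300), (400, 500), (600, 810)]
                )
            ]
        )
        (r,) = match_assembly(q, make_assembly([four_exon_ref]))
        assert r.correctly_assembled
        assert r.exon_completeness == 100.0

    def test_strand_mismatch_not_matched(self, four_exon_ref):
        q = make_assembly(
            [
                make_transcript(
                    "q",
                    [(0, 100), (200, 300), (400, 500), (600, 700)],
                    strand="-",
                )
            ]
        )
        (r,) = match_assembly(q, make_assembly([four_exon_ref]))
        assert not r.correctly_assembled
        assert r.splice_completeness == 0.0

    @pytest.mark.parametrize(
        "q_iv,expected", [((0, 100), True), ((5, 100), True), ((60, 160), False)]
    )
    def test_single_exon_reciprocal_overlap(self, q_iv, expected):
        ref = make_assembly([make_transcript("r", [(0, 100)])])
        q = make_assembly([make_transcript("q", [q_iv])])
        (r,) = match_assembly(q, ref, single_exon_overlap=0.9)
        assert r.correctly_assembled == expected

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            match_assembly(make_assembly([]), make_assembly([]))

    def test_monotone_in_query(self, four_exon_ref):
        small = make_assembly([make_transcript("q1", [(0, 100), (200, 300)])])
        bigger = make_assembly(
            [
                make_transcript("q1", [(0, 100), (200, 300)]),
                make_transcript("q2", [(400, 500), (600, 700)]),
            ]
        )
        ref = make_assembly([four_exon_ref])
        (a,) = match_assembly(small, ref)
        (b,) = match_assembly(bigger, ref)
        assert b.splice_completeness >= a.splice_completeness
        assert b.exon_completeness >= a.exon_completeness


class TestCompletenessTable:
    def _results(self, query, ref):
        return match_assembly(query, ref)

    def test_shares(self, four_exon_ref):
        refs = [
            four_exon_ref.with_(transcript_id="r1"),
            make_transcript("r2", [(1000, 1300)], coding_class="coding"),
            make_transcript("r3", [(2000, 2300)], coding_class="noncoding"),
        ]
        query = make_assembly(
            [
                make_transcript("q1", [(0, 100), (200, 300)]),  # partial of r1
                make_transcript("q2", [(1000, 1300)]),  # exact r2
            ]
        )
        res = match_assembly(query, make_assembly(refs))
        classes = {"r1": "coding", "r2": "coding", "r3": "noncoding"}
        summ = completeness_table(res, classes)
        row = summ.row("coding", "exon")
        assert row["complete"] == 50.0  # r2 of {r1, r2}
        assert row["missing"] == 0.0
        assert row["partial"] == 50.0
        ncrow = summ.row("noncoding", "exon")
        assert ncrow["missing"] == 100.0

    def test_replicate_averaging_with_sd(self, four_exon_ref):
        ref = make_assembly([four_exon_ref.with_(transcript_id="r1")])
        classes = {"r1": "coding"}
        hit = match_assembly(
            make_assembly([four_exon_ref.with_(transcript_id="q")]), ref
        )
        miss = match_assembly(
            make_assembly([make_transcript("q", [(9000, 9300)])]), ref
        )
        summ = completeness_table([hit, miss], classes)
        row = summ.row("coding", "splice")
        assert row["complete"] == 50.0
        assert row["complete_sd"] == 50.0

    def test_missing_class_label_named(self, four_exon_ref):
        ref = make_assembly([four_exon_ref])
        res = match_assembly(ref, ref)
        with pytest.raises(ValueError, match="ref1"):
            completeness_table(res, {})


class TestSensitivityPrecision:
    def test_identity_gives_unit_metrics(self, four_exon_ref):
        asm = make_assembly(
            [
                four_exon_ref,
                make_transcript("n1", [(1000, 1400)], coding_class="noncoding"),
            ]
        )
        classes = {t.transcript_id: t.coding_class for t in asm}
        res = match_assembly(asm, asm)
        assert sensitivity(res, classes).sensitivity == {
            "coding": 1.0,
            "noncoding": 1.0,
            "overall": 1.0,
        }
        assert precision(asm, asm).precision["overall"] == 1.0

    def test_empty_query_undefined_precision(self, four_exon_ref):
        ref = make_assembly([four_exon_ref])
        res = match_assembly(make_assembly([]), ref)
        s = sensitivity(res, {"ref1": "coding"})
        assert s.sensitivity["coding"] == 0.0
        p = precision(make_assembly([]), ref)
        assert p.precision["overall"] is None  # undefined, not 0

    def test_hand_counted_fixture(self):
        """10 reference (6 coding); query correctly assembles 3 coding + 1
        noncoding and adds 2 noise transcripts: coding sensitivity 0.5,
        noncoding 0.25, overall precision 4/6."""
        refs, queries = [], []
        pos = 0
        for i in range(10):
            cls = "coding" if i < 6 else "noncoding"
            refs.append(
                make_transcript(
                    f"r{i}", [(pos, pos + 100), (pos + 200, pos + 300)],
                    coding_class=cls,
                )
            )
            pos += 1000
        for i in (0, 1, 2, 6):  # 3 coding + 1 noncoding recovered exactly
            refs[i] = refs[i]
            queries.append(
                refs[i].with_(transcript_id=f"q{i}")
            )
        for j in range(2):  # noise
            base = 50_000 + j * 5000
            queries.append(
                make_transcript(
                    f"noise{j}", [(base, base + 100), (base + 300, base + 400)],
                    coding_class="noncoding",
                )
            )
        query = make_assembly(queries)
        reference = make_assembly(refs)
        classes = {t.transcript_id: t.coding_class for t in reference}
        res = match_assembly(query, reference)
        s = sensitivity(res, classes).sensitivity
        assert s["coding"] == 0.5
        assert s["noncoding"] == 0.25
        p = precision(query, reference).precision
        assert p["overall"] == pytest.approx(4 / 6)


class TestClassifyAnnotationStatus:
    @pytest.fixture()
    def annotation(self, four_exon_ref):
        return make_assembly([four_exon_ref.with_(transcript_id="ann1")])

    def test_exact_copy_is_annotated(self, annotation, four_exon_ref):
        q = make_assembly([four_exon_ref.with_(transcript_id="q")])
        assert classify_annotation_status(q, annotation)["q"] == "annotated"

    def test_unknown_chromosome_is_novel(self, annotation):
        q = make_assembly([make_transcript("q", [(0, 300)], chrom="chrZ")])
        assert classify_annotation_status(q, annotation)["q"] == "novel"

    def test_extra_junction_is_variant(self, annotation):
        q = make_assembly(
            [
                make_transcript(
                    "q",
                    [(0, 100), (200, 300), (400, 500), (600, 640), (660, 700)],
                )
            ]
        )
        assert classify_annotation_status(q, annotation)["q"] == "variant"

    def test_exon_overlap_is_strand_agnostic(self, annotation):
        q = make_assembly([make_transcript("q", [(0, 300)], strand="-")])
        assert classify_annotation_status(q, annotation)["q"] == "variant"


class TestTeOverlap:
    def test_exonic_overlap_flags(self):
        asm = make_assembly([make_transcript("t", [(100, 200), (400, 500)])])
        out = annotate_te_overlap(asm, [GenomicInterval("chr1", 150, 160)])
        assert out.transcripts["t"].te_containing is True

    def test_intronic_te_not_flagged(self):
        asm = make_assembly([make_transcript("t", [(100, 200), (400, 500)])])
        out = annotate_te_overlap(asm, [GenomicInterval("chr1", 250, 350)])
        assert out.transcripts["t"].te_containing is False

    def test_no_te_list_all_false(self):
        asm = make_assembly([make_transcript("t", [(100, 200)])])
        out = annotate_te_overlap(asm, [])
        assert out.transcripts["t"].te_containing is False

    def test_min_overlap_threshold(self):
        asm = make_assembly([make_transcript("t", [(100, 200)])])
        te = [GenomicInterval("chr1", 195, 300)]
        assert annotate_te_overlap(asm, te, min_overlap=5).transcripts[
            "t"
        ].te_containing
        assert not annotate_te_overlap(asm, te, min_overlap=6).transcripts[
            "t"
        ].te_containing

    def test_order_independent(self):
        rng = np.random.default_rng(0)
        asm = make_assembly(
            [make_transcript(f"t{i}", [(i * 1000, i * 1000 + 500)]) for i in range(20)]
        )
        tes = [
            GenomicInterval("chr1", int(s), int(s) + 80)
            for s in rng.integers(0, 20_000, 30)
        ]
        a = annotate_te_overlap(asm, tes)
        b = annotate_te_overlap(asm, list(reversed(tes)))
        assert {t.transcript_id: t.te_containing for t in a} == {
            t.transcript_id: t.te_containing for t in b
        }


class TestRecurrenceFilter:
    def _assemblies(self):
        base = make_transcript("t", [(0, 100), (200, 300)])
        other = make_transcript("u", [(1000, 1100), (1300, 1400)])
        single = make_transcript("s", [(5000, 5400)])
        assemblies = []
        for i in range(5):
            ts = []
            if i < 3:
                ts.append(base.with_(transcript_id=f"t_{i}"))
            if i < 2:
                ts.append(other.with_(transcript_id=f"u_{i}"))
            if i in (0, 2, 4):
                ts.append(single.with_(transcript_id=f"s_{i}"))
            assemblies.append(make_assembly(ts, sample_id=f"a{i}"))
        return assemblies

    def test_min_one_is_union_of_chains(self):
        assemblies = self._assemblies()
        out = recurrence_filter(assemblies, 1)
        assert len(out) == 3  # base chain, other chain, single-exon cluster

    def test_threshold_excludes_rare_chains(self):
        assemblies = self._assemblies()
        out = recurrence_filter(assemblies, 3)
        recs = {intron_chain(t)[2]: t.recurrence for t in out}
        assert len(out) == 2  # base (3 samples) + single cluster (3 samples)
        assert set(recs.values()) == {3}
        assert recurrence_filter(assemblies, 4).transcripts == {}

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(42)
        assemblies = [random_instance(rng, 20)[0] for _ in range(5)]
        tally = bf_recurrence_counts(assemblies)
        for min_s in (2, 5):
            out = recurrence_filter(assemblies, min_s)
            got = {
                intron_chain(t): t.recurrence for t in out if t.n_exons > 1
            }
            expected = {c: n for c, n in tally.items() if n >= min_s}
            assert got == expected

    def test_min_samples_below_one_rejected(self):
        with pytest.raises(ValueError):
            recurrence_filter([make_assembly([])], 0)


class TestBruteForceEquivalence:
    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            query, reference = random_instance(rng, 30)
            res = match_assembly(query, reference)
            oracle = bf_match(query, reference)
            for r in res:
                exp_exon, exp_splice, exp_correct, exp_best = oracle[r.reference_id]
                assert r.exon_completeness == exp_exon
                assert r.splice_completeness == exp_splice
                assert r.correctly_assembled == exp_correct
                assert r.best_query_id == exp_best
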