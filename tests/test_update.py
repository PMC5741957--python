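"""Gene merging, structural updates and splice-event classification."""

import numpy as np
import pytest

from droughtgenes import (
    GeneModel,
    GenomicInterval,
    Transcript,
    TranscriptAlignment,
    apply_update,
    classify_splice_events,
    merge_genes,
    summarize_updates,
    two_round_compare,
    validate_model,
)
from droughtgenes.overlap import OverlapCategory, call_transcript
from droughtgenes.synthetic import gen_annotation, gen_update_evidence
from droughtgenes.update import SpliceEventType, UpdateKind, UpdateRecord


def aln(qid, seq_id, blocks, strand="+"):
    return TranscriptAlignment(
        qid, tuple(GenomicInterval(seq_id, s, e, strand) for s, e in blocks), 99, 99
    )


def tx(tid, exons, strand="+", seq_id="chr1"):
    return Transcript(tid, tuple(GenomicInterval(seq_id, s, e, strand) for s, e in exons))


class TestMergeGenes:
    def test_merged_id_joins_in_genomic_order(self):
        g1 = GeneModel.from_exons("Sb04g008510", "chr4", [(9_869_026, 9_875_000)], "+")
        g2 = GeneModel.from_exons("Sb04g008530", "chr4", [(9_880_000, 9_888_743)], "+")
        ev = aln("q", "chr4", [(9_870_000, 9_888_000)])
        merged = merge_genes([g2, g1], ev)  # order given reversed on purpose
        assert merged.gene_id == "Sb04g008510_Sb04g008530"
        assert (merged.span.start, merged.span.end) == (9_869_026, 9_888_743)

    def test_merged_span_is_envelope(self):
        g1 = GeneModel.from_exons("a", "chr1", [(100, 200)], "+")
        g2 = GeneModel.from_exons("b", "chr1", [(400, 500)], "+")
        merged = merge_genes([g1, g2], aln("q", "chr1", [(150, 450)]))
        assert (merged.span.start, merged.span.end) == (100, 500)
        assert validate_model(merged) == []

    def test_random_merges_match_envelope_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            starts = np.sort(rng.integers(1, 10_000, size=3))
            genes = [
                GeneModel.from_exons(
                    f"g{i}", "chr1", [(int(s) * 10, int(s) * 10 + 200)], "+"
                )
                for i, s in enumerate(starts)
            ]
            ev = aln("q", "chr1", [(genes[0].span.start + 1, genes[-1].span.end - 1)])
            merged = merge_genes(genes, ev)
            lo = min([g.span.start for g in genes] + [ev.span.start])
            hi = max([g.span.end for g in genes] + [ev.span.end])
            assert (merged.span.start, merged.span.end) == (lo, hi)
            # all transcripts carried plus the evidence-derived one
            assert len(merged.transcripts) == sum(len(g.transcripts) for g in genes) + 1

    def test_different_seq_ids_refused(self):
        g1 = GeneModel.from_exons("a", "chr1", [(100, 200)], "+")
        g2 = GeneModel.from_exons("b", "chr2", [(400, 500)], "+")
        with pytest.raises(ValueError, match="seq_id"):
            merge_genes([g1, g2], aln("q", "chr1", [(150, 450)]))


class TestApplyUpdate:
    def test_perfect_identical_evidence_changes_nothing(self):
        g = GeneModel.from_exons("g", "chr1", [(100, 150), (200, 260)], "+")
        ev = aln("q", "chr1", [(100, 150), (200, 260)])
        updated, records = apply_update(g, ev, OverlapCategory.PERFECT)
        assert updated == g and records == []

    def test_three_prime_extension_yields_utr3_and_span(self):
        g = GeneModel.from_exons("g", "chr1", [(100, 200)], "+")
        ev = aln("q", "chr1", [(100, 260)])
        updated, records = apply_update(g, ev, OverlapCategory.EXT_3_SHARE_5)
        kinds = sorted(r.update_kind.value for r in records)
        assert kinds == ["EXTENDED_SPAN", "NEW_UTR3"]
        assert (updated.span.start, updated.span.end) == (100, 260)
        assert updated.representative.utr3[0].start == 201
        assert validate_model(updated) == []

    def test_minus_strand_orients_utrs(self):
        g = GeneModel.from_exons("g", "chr1", [(100, 200)], "-")
        ev = aln("q", "chr1", [(100, 260)], strand="-")
        _, records = apply_update(g, ev, OverlapCategory.EXT_5_SHARE_3)
        kinds = {r.update_kind.value for r in records}
        assert kinds == {"NEW_UTR5", "EXTENDED_SPAN"}

    def test_merged_category_rejected(self):
        g = GeneModel.from_exons("g", "chr1", [(100, 200)], "+")
        with pytest.raises(ValueError):
            apply_update(g, aln("q", "chr1", [(100, 200)]), OverlapCategory.MERGED)

    def test_planted_event_counts_recovered(self):
        genes, _ = gen_annotation(80, 3, seed=7)
        evidence, truth = gen_update_evidence(genes, 10, 10, 10, seed=5)
        calls = [(a, call_transcript(a, genes)) for a, _g in evidence]
        updated, records, second = two_round_compare(genes, calls)
        counts = {k.value: 0 for k in UpdateKind}
        for r in records:
            counts[r.update_kind.value] += 1
        assert counts["NEW_EXON"] == truth.update_counts["NEW_EXON"] == 10
        assert counts["NEW_UTR5"] == truth.update_counts["NEW_UTR5"] == 10
        assert counts["NEW_UTR3"] == truth.update_counts["NEW_UTR3"] == 10
        for m in updated:
            assert validate_model(m) == []
        # second round is a fixed point: re-applying the evidence adds nothing
        assert second == []

    def test_idempotent_on_single_gene(self):
        g = GeneModel.from_exons("g", "chr1", [(100, 200)], "+")
        ev = aln("q", "chr1", [(100, 260)])
        updated, first = apply_update(g, ev, OverlapCategory.EXT_3_SHARE_5)
        again, second = apply_update(updated, ev, OverlapCategory.PERFECT)
        assert first and second == [] and again == updated


class TestSpliceEvents:
    def test_single_exon_vs_spliced_is_retained_intron(self):
        a = tx("a", [(1, 30)])
        b = tx("b", [(1, 10), (21, 30)])
        assert classify_splice_events(a, b) == [SpliceEventType.RETAINED_INTRON]
        assert classify_splice_events(b, a) == [SpliceEventType.SKIPPED_EXON]

    def test_shared_donor_different_acceptor(self):
        a = tx("a", [(1, 10), (21, 40)])  # intron [11,20]
        b = tx("b", [(1, 10), (26, 40)])  # intron [11,25], same donor 11
        events = classify_splice_events(a, b)
        assert SpliceEventType.ALT_ACCEPTOR in events
        assert SpliceEventType.ALT_DONOR not in events

    def test_shared_acceptor_different_donor(self):
        a = tx("a", [(1, 10), (21, 40)])  # intron [11,20]
        b = tx("b", [(1, 14), (21, 40)])  # intron [15,20], same acceptor 20
        events = classify_splice_events(a, b)
        assert SpliceEventType.ALT_DONOR in events

    def test_donor_acceptor_roles_follow_strand(self):
        a = tx("a", [(1, 10), (21, 40)], strand="-")
        b = tx("b", [(1, 10), (26, 40)], strand="-")
        # on the minus strand the shared coordinate 11 is the acceptor side
        events = classify_splice_events(a, b)
        assert SpliceEventType.ALT_DONOR in events

    def test_cassette_exon_orientation(self):
        a = tx("a", [(1, 10), (15, 20), (25, 30)])
        b = tx("b", [(1, 10), (25, 30)])
        # a expresses an internal exon inside b's intron; b skips it
        assert SpliceEventType.RETAINED_INTRON in classify_splice_events(a, b)
        assert SpliceEventType.SKIPPED_EXON in classify_splice_events(b, a)

    def test_terminal_exon_in_intron(self):
        a = tx("a", [(1, 15)])  # ends at 15, inside b's intron [11,20]
        b = tx("b", [(1, 10), (21, 30)])
        events = classify_splice_events(a, b)
        assert SpliceEventType.ENDS_IN_INTRON in events

    def test_non_overlapping_transcripts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_splice_events(tx("a", [(1, 10)]), tx("b", [(50, 60)]))

    def test_swap_duality_on_random_chains(self):
        """Swapping arguments maps RETAINED_INTRON<->SKIPPED_EXON and fixes
        ALT_ACCEPTOR/ALT_DONOR, over random overlapping exon chains."""
        rng = np.random.default_rng(41)
        dual = {
            "RETAINED_INTRON": "SKIPPED_EXON",
            "SKIPPED_EXON": "RETAINED_INTRON",
            "ALT_ACCEPTOR": "ALT_ACCEPTOR",
            "ALT_DONOR": "ALT_DONOR",
            "ALT_EXON": "ALT_EXON",
        }
        directional = {"RETAINED_INTRON", "SKIPPED_EXON", "ALT_ACCEPTOR", "ALT_DONOR", "ALT_EXON"}

        def random_chain(tid):
            n = int(rng.integers(1, 5))
            pos = int(rng.integers(1, 20))
            exons = []
            for _ in range(n):
                e = pos + int(rng.integers(5, 30))
                exons.append((pos, e))
                pos = e + 1 + int(rng.integers(5, 25))
            return tx(tid, exons)

        checked = 0
        while checked < 100:
            a, b = random_chain("a"), random_chain("b")
            if not a.span.overlaps(b.span):
                continue
            checked += 1
            fwd = [e.value for e in classify_splice_events(a, b) if e.value in directional]
            rev = [e.value for e in classify_splice_events(b, a) if e.value in directional]
            assert sorted(dual[e] for e in fwd) == sorted(rev)

    def test_events_match_independent_inclusion_oracle(self):
        """Retained/skipped calls equal a directly-coded interval-logic scan."""
        rng = np.random.default_rng(43)

        def chains():
            n = int(rng.integers(1, 5))
            pos = int(rng.integers(1, 15))
            exons = []
            for _ in range(n):
                e = pos + int(rng.integers(4, 25))
                exons.append((pos, e))
                pos = e + 1 + int(rng.integers(4, 20))
            return exons

        def introns(exons):
            return [
                (l[1] + 1, r[0] - 1) for l, r in zip(exons, exons[1:]) if r[0] - l[1] >= 2
            ]

        for _ in range(200):
            ea, eb = chains(), chains()
            a, b = tx("a", ea), tx("b", eb)
            if not a.span.overlaps(b.span):
                continue
            got = classify_splice_events(a, b)
            n_ret = sum(1 for e in got if e is SpliceEventType.RETAINED_INTRON)
            n_skip = sum(1 for e in got if e is SpliceEventType.SKIPPED_EXON)
            want_ret = sum(
                1
                for i in introns(eb)
                for x in ea
                if x[0] <= i[0] and i[1] <= x[1]
            ) + sum(
                1
                for x in ea[1:-1]
                for i in introns(eb)
                if i[0] <= x[0] and x[1] <= i[1]
            )
            want_skip = sum(
                1
                for i in introns(ea)
                for x in eb
                if x[0] <= i[0] and i[1] <= x[1]
            ) + sum(
                1
                for x in eb[1:-1]
                for i in introns(ea)
                if i[0] <= x[0] and x[1] <= i[1]
            )
            assert n_ret == want_ret and n_skip == want_skip


class TestSummarizeUpdates:
    def test_empty_records_all_zero(self):
        s = summarize_updates([], total_genes=100)
        assert s["distinct_genes_updated"] == 0
        assert s["fraction_updated_pct"] == 0.0
        assert all(v == 0 for v in s["counts_per_kind"].values())

    def test_three_records_two_genes_of_twenty(self):
        iv = GenomicInterval("chr1", 1, 100)
        iv2 = GenomicInterval("chr1", 1, 120)
        records = [
            UpdateRecord("g1", UpdateKind.NEW_EXON, "q1", iv, iv),
            UpdateRecord("g1", UpdateKind.NEW_UTR3, "q2", iv, iv2),
            UpdateRecord("g2", UpdateKind.NEW_UTR5, "q3", iv, iv2),
        ]
        s = summarize_updates(records, total_genes=20)
        assert s["distinct_genes_updated"] == 2
        assert s["fraction_updated_pct"] == 10.0

    def test_summary_equals_recount(self):
        genes, _ = gen_annotation(80, 3, seed=7)
        evidence, _ = gen_update_evidence(genes, 8, 8, 8, seed=5)
        calls = [(a, call_transcript(a, genes)) for a, _g in evidence]
        _, records, _ = two_round_compare(genes, calls)
        s = summarize_updates(records, total_genes=len(genes))
        for kind in UpdateKind:
            assert s["counts_per_kind"][kind.value] == sum(
                1 for r in records if r.update_kind is kind
            )
        assert s["distinct_genes_updated"] == len({r.gene_id for r in records})
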