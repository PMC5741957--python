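"""Novel-gene screening criteria, completeness and exon/intron accounting."""

import numpy as np
import pytest

from droughtgenes import (
    CompletenessClass,
    GeneModel,
    GenomicInterval,
    NovelGeneCandidate,
    PipelineConfig,
    Transcript,
    apply_filter,
    classify_completeness,
    exon_intron_stats,
    intergenic_distance,
    summarize_novel_genes,
)
from droughtgenes.synthetic import gen_annotation


def gene(gene_id, start, end, seq_id="chr1", strand="+", **kw):
    return GeneModel.from_exons(gene_id, seq_id, [(start, end)], strand, **kw)


def candidate(start, end, score=0.9, evidence="ab_initio", support=None, **kw):
    return NovelGeneCandidate(
        gene("cand", start, end, **kw), score, evidence, support
    )


class TestIntergenicDistance:
    def test_strictly_between_counts(self):
        left, right = intergenic_distance(
            gene("c", 120, 180), [gene("a", 1, 100), gene("b", 201, 300)]
        )
        assert (left, right) == (19, 20)

    def test_alone_on_scaffold_is_unbounded(self):
        assert intergenic_distance(gene("c", 120, 180), []) == (None, None)

    def test_adjacent_gene_gives_zero_gap(self):
        left, _ = intergenic_distance(gene("c", 120, 180), [gene("a", 1, 119)])
        assert left == 0

    def test_overlapping_neighbour_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            intergenic_distance(gene("c", 120, 180), [gene("a", 150, 300)])

    def test_other_seq_ids_ignored(self):
        left, right = intergenic_distance(
            gene("c", 120, 180), [gene("a", 1, 170, seq_id="chr9")]
        )
        assert (left, right) == (None, None)


class TestApplyFilter:
    def test_short_candidate_fails_mandatory_length(self, cfg):
        v = apply_filter(candidate(1000, 1149, score=0.9), [], cfg)
        assert not v.c2_length and not v.passed
        assert v.c1_no_overlap  # other criteria may still hold

    def test_length_threshold_exclusive(self, cfg):
        # span of exactly 200 bases fails ("greater than 200"); 201 passes
        assert not apply_filter(candidate(1, 200), [], cfg).c2_length
        assert apply_filter(candidate(1, 201), [], cfg).c2_length

    def test_score_satisfies_disjunction(self, cfg):
        ann = [gene("a", 1, 100), gene("b", 600, 700)]
        v = apply_filter(candidate(300, 549, score=0.6), ann, cfg)
        assert v.c3_score and v.passed

    def test_overlap_with_existing_gene_is_fatal(self, cfg):
        ann = [gene("a", 400, 600)]
        v = apply_filter(candidate(500, 800, score=0.9), ann, cfg)
        assert not v.c1_no_overlap and not v.passed

    def test_ab_initio_never_satisfies_support(self, cfg):
        v = apply_filter(candidate(300, 549, evidence="ab_initio"), [], cfg)
        assert not v.c4_support

    def test_support_threshold_exclusive(self, cfg):
        kw = dict(score=0.0, evidence="homology")
        assert not apply_filter(candidate(300, 549, support=50.0, **kw), [], cfg).c4_support
        assert apply_filter(candidate(300, 549, support=50.1, **kw), [], cfg).c4_support

    def test_random_candidates_match_boolean_oracle(self, cfg):
        genes, _ = gen_annotation(40, 2, seed=19)
        rng = np.random.default_rng(20)
        for _ in range(1000):
            seq_id = f"chr{int(rng.integers(1, 3))}"
            s = int(rng.integers(1, 12_000))
            length = int(rng.integers(100, 700))
            score = float(rng.uniform(0, 1))
            evidence = "homology" if rng.random() < 0.5 else "ab_initio"
            support = float(rng.uniform(0, 100)) if evidence == "homology" else None
            cand = NovelGeneCandidate(
                gene("cand", s, s + length - 1, seq_id=seq_id),
                score,
                evidence,
                support,
            )
            v = apply_filter(cand, genes, cfg)
            span = cand.model.span
            c1 = not any(
                g.seq_id == span.seq_id and g.span.overlaps(span) for g in genes
            )
            c2 = span.length > 200
            c3 = score >= 0.5
            c4 = evidence == "homology" and support is not None and support > 50
            if c1:
                gaps = []
                for side in (0, 1):
                    cands = [
                        g.span
                        for g in genes
                        if g.seq_id == span.seq_id
                        and (g.span.end < span.start if side == 0 else g.span.start > span.end)
                    ]
                    if not cands:
                        gaps.append(None)
                    elif side == 0:
                        gaps.append(span.start - max(c.end for c in cands) - 1)
                    else:
                        gaps.append(min(c.start for c in cands) - span.end - 1)
                c5 = all(g is None or g >= 100 for g in gaps)
            else:
                c5 = False
            assert v.passed == (c1 and c2 and (c3 or c4 or c5))

    def test_strict_mode_requires_all_five(self):
        cfg = PipelineConfig(strict_filter=True)
        v = apply_filter(candidate(300, 549, score=0.9, evidence="ab_initio"), [], cfg)
        assert v.c3_score and v.c5_distance_strand and not v.passed  # c4 fails

    def test_relaxing_thresholds_never_shrinks_pass_set(self):
        genes, _ = gen_annotation(30, 2, seed=29)
        rng = np.random.default_rng(30)
        cands = []
        for _ in range(200):
            s = int(rng.integers(1, 9000))
            cands.append(
                NovelGeneCandidate(
                    gene("c", s, s + int(rng.integers(100, 600)),
                         seq_id=f"chr{int(rng.integers(1, 3))}"),
                    float(rng.uniform(0, 1)),
                    "homology",
                    float(rng.uniform(0, 100)),
                )
            )
        tight = PipelineConfig()
        for relaxed in (
            PipelineConfig(min_gene_length=100),
            PipelineConfig(min_score=0.2),
            PipelineConfig(min_evidence_support=10),
            PipelineConfig(min_intergenic_distance=10),
        ):
            passed_tight = {
                i for i, c in enumerate(cands) if apply_filter(c, genes, tight).passed
            }
            passed_relaxed = {
                i for i, c in enumerate(cands) if apply_filter(c, genes, relaxed).passed
            }
            assert passed_tight <= passed_relaxed


class TestCompleteness:
    def _cand(self, utr5=False, utr3=False, codons=False):
        exons = (GenomicInterval("chr1", 100, 400),)
        tx = Transcript(
            "t",
            exons,
            (GenomicInterval("chr1", 100, 130),) if utr5 else (),
            (GenomicInterval("chr1", 370, 400),) if utr3 else (),
            has_start_codon=codons,
            has_stop_codon=codons,
        )
        return NovelGeneCandidate(
            GeneModel.from_transcripts("g", (tx,)), 0.8, "ab_initio"
        )

    def test_both_utrs_complete(self):
        assert classify_completeness(self._cand(True, True)) is CompletenessClass.COMPLETE

    def test_only_3utr(self):
        assert classify_completeness(self._cand(False, True)) is CompletenessClass.SEMI_3UTR

    def test_only_5utr(self):
        assert classify_completeness(self._cand(True, False)) is CompletenessClass.SEMI_5UTR

    def test_no_utr_with_codons_is_partial(self):
        assert classify_completeness(self._cand(codons=True)) is CompletenessClass.PARTIAL


class TestExonIntronStats:
    def test_chromosome_scale_row(self):
        """28 single-transcript genes with 66 exons in total: 38 introns and
        a mean of 2.4 exons per gene."""
        rng = np.random.default_rng(47)
        counts = rng.multinomial(66 - 28, np.ones(28) / 28) + 1
        assert counts.sum() == 66
        genes = []
        pos = 1
        for i, n_ex in enumerate(counts):
            exons = []
            for _ in range(n_ex):
                exons.append((pos, pos + 99))
                pos += 200
            genes.append(GeneModel.from_exons(f"g{i}", "Chr1", exons))
            pos += 500
        row = exon_intron_stats(genes).iloc[0]
        assert row["genes"] == 28
        assert row["exons"] == 66
        assert row["introns"] == 38
        assert row["mean_exons_per_gene"] == 2.4

    def test_single_exon_gene(self):
        row = exon_intron_stats([gene("g", 1, 500)]).iloc[0]
        assert row["introns"] == 0 and row["mean_exons_per_gene"] == 1.0

    def test_conservation_identity_per_group(self):
        genes, _ = gen_annotation(120, 4, seed=51)
        table = exon_intron_stats(genes)
        assert (table["introns"] == table["exons"] - table["genes"]).all()


def test_summary_shares_reproduce_reported_composition():
    """210 accepted novel genes with the reported composition yield the
    reported one-decimal shares."""
    cands = []
    for i in range(210):
        utr5 = i < 12 or 27 <= i < 29
        utr3 = i < 27
        single = i < 105
        exons = [(1000 * i + 1, 1000 * i + 300)]
        if not single:
            exons.append((1000 * i + 400, 1000 * i + 600))
        tx = Transcript(
            f"t{i}",
            tuple(GenomicInterval("chr1", s, e) for s, e in exons),
            (GenomicInterval("chr1", 1000 * i + 1, 1000 * i + 20),) if utr5 else (),
            (GenomicInterval("chr1", exons[-1][1] - 20, exons[-1][1]),) if utr3 else (),
            has_start_codon=True,
            has_stop_codon=True,
        )
        cands.append(
            NovelGeneCandidate(
                GeneModel.from_transcripts(f"g{i}", (tx,)),
                0.8,
                "homology" if i < 112 else "ab_initio",
                90.0 if i < 112 else None,
                drought_responsive=i < 146,
            )
        )
    s = summarize_novel_genes(cands)
    assert s["total"] == 210
    assert s["drought_responsive_pct"] == 69.5   # 146/210
    assert s["single_exon_pct"] == 50.0          # 105/210
    assert s["complete_pct"] == 5.7              # 12/210
    assert s["at_least_one_utr"] == 29           # 12 + 15 + 2
    assert s["homology_evidence_pct"] == 53.3    # 112/210
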