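"""Screening of predicted intergenic (novel) gene models.

Five criteria gate a predicted gene: (1) no overlap with any existing gene and
(2) span length above 200 bp are mandatory; at least one of (3) predictor
confidence score >= 0.5, (4) homology-based evidence support above 50%, or
(5) a clean neighbourhood — at least 100 bp of intergenic distance to the
nearest gene on either side, regardless of its strand — must also hold.
A strict mode requires all five.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import GeneModel, PipelineConfig, percent, round1


@dataclass(frozen=True)
class NovelGeneCandidate:
    """A predicted intergenic gene with its predictor metadata."""

    model: GeneModel
    score: float                       # predictor confidence in [0,1]
    evidence_type: str                 # "homology" | "ab_initio"
    evidence_support: float | None = None  # %, present iff homology
    drought_responsive: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 1):
            raise ValueError(f"score must be in [0,1], got {self.score}")
        if self.evidence_type not in ("homology", "ab_initio"):
            raise ValueError(f"unknown evidence_type {self.evidence_type!r}")
        if self.evidence_support is not None and not (0 <= self.evidence_support <= 100):
            raise ValueError("evidence_support must be in [0,100]")


@dataclass(frozen=True)
class FilterVerdict:
    candidate_id: str
    c1_no_overlap: bool
    c2_length: bool
    c3_score: bool
    c4_support: bool
    c5_distance_strand: bool
    passed: bool

    def __post_init__(self) -> None:
        expected = self.c1_no_overlap and self.c2_length and (
            self.c3_score or self.c4_support or self.c5_distance_strand
        )
        # strict mode produces passed == all five; both satisfy passed => expected
        if self.passed and not expected:
            raise ValueError("passed verdict inconsistent with criteria")


class CompletenessClass(enum.Enum):
    COMPLETE = "COMPLETE"    # both UTRs present
    SEMI_3UTR = "SEMI_3UTR"  # 3' UTR only
    SEMI_5UTR = "SEMI_5UTR"  # 5' UTR only
    PARTIAL = "PARTIAL"      # no UTR; start and stop codons flagged


UNBOUNDED = None
"""Gap marker used when a candidate has no neighbour on a side."""


def intergenic_distance(
    candidate: GeneModel, neighbours: Sequence[GeneModel]
) -> tuple[int | None, int | None]:
    """Strictly-between base counts to the nearest neighbour on each side.

    Neighbours on other seq_ids are ignored; a missing neighbour yields the
    unbounded marker (None).  An overlapping neighbour violates the novelty
    precondition and is an error.
    """
    span = candidate.span
    left_gap: int | None = UNBOUNDED
    right_gap: int | None = UNBOUNDED
    for n in neighbours:
        if n.seq_id != span.seq_id:
            continue
        ns = n.span
        if ns.overlaps(span):
            raise ValueError(
                f"neighbour {n.gene_id} overlaps candidate {candidate.gene_id}"
            )
        if ns.end < span.start:
            gap = span.start - ns.end - 1
            if left_gap is UNBOUNDED or gap < left_gap:
                left_gap = gap
        else:
            gap = ns.start - span.end - 1
            if right_gap is UNBOUNDED or gap < right_gap:
                right_gap = gap
    return left_gap, right_gap


def apply_filter(
    cand: NovelGeneCandidate,
    annotation: Sequence[GeneModel],
    cfg: PipelineConfig | None = None,
) -> FilterVerdict:
    """Evaluate the five screening criteria for one candidate.

    c1: shares no base with any existing gene (strand-blind — a novel locus
    may not sit under an annotated gene on either strand);
    c2: span length strictly greater than ``min_gene_length``;
    c3: score >= ``min_score``;
    c4: homology evidence with support strictly above ``min_evidence_support``
    (ab initio predictions fail c4);
    c5: every finite intergenic gap >= ``min_intergenic_distance`` — the
    neighbour-orientation rule, applied identically to same- and
    opposite-strand neighbours.
    """
    cfg = cfg or PipelineConfig()
    span = cand.model.span
    overlapping = [
        g for g in annotation if g.seq_id == span.seq_id and g.span.overlaps(span)
    ]
    c1 = not overlapping
    c2 = span.length > cfg.min_gene_length
    c3 = cand.score >= cfg.min_score
    c4 = (
        cand.evidence_type == "homology"
        and cand.evidence_support is not None
        and cand.evidence_support > cfg.min_evidence_support
    )
    if c1:
        left, right = intergenic_distance(cand.model, annotation)
        c5 = all(
            gap is UNBOUNDED or gap >= cfg.min_intergenic_distance
            for gap in (left, right)
        )
    else:
        c5 = False
    if cfg.strict_filter:
        passed = c1 and c2 and c3 and c4 and c5
    else:
        passed = c1 and c2 and (c3 or c4 or c5)
    return FilterVerdict(cand.model.gene_id, c1, c2, c3, c4, c5, passed)


def classify_completeness(cand: NovelGeneCandidate) -> CompletenessClass:
    """Gene-structure completeness from the representative transcript's UTRs."""
    rep = cand.model.representative
    has5 = bool(rep.utr5)
    has3 = bool(rep.utr3)
    if has5 and has3:
        return CompletenessClass.COMPLETE
    if has3:
        return CompletenessClass.SEMI_3UTR
    if has5:
        return CompletenessClass.SEMI_5UTR
    return CompletenessClass.PARTIAL


def completeness_summary(cands: Sequence[NovelGeneCandidate]) -> dict:
    """Counts per completeness class plus the at-least-one-UTR total."""
    counts = {c.value: 0 for c in CompletenessClass}
    for cand in cands:
        counts[classify_completeness(cand).value] += 1
    counts["AT_LEAST_ONE_UTR"] = (
        counts["COMPLETE"] + counts["SEMI_3UTR"] + counts["SEMI_5UTR"]
    )
    return counts


def summarize_novel_genes(cands: Sequence[NovelGeneCandidate]) -> dict:
    """Headline shares over a set of accepted novel genes (one-decimal %)."""
    n = len(cands)
    single_exon = sum(1 for c in cands if len(c.model.representative.exons) == 1)
    drought = sum(1 for c in cands if c.drought_responsive)
    homology = sum(1 for c in cands if c.evidence_type == "homology")
    comp = completeness_summary(cands)
    return {
        "total": n,
        "drought_responsive": drought,
        "drought_responsive_pct": percent(drought, n),
        "single_exon": single_exon,
        "single_exon_pct": percent(single_exon, n),
        "complete": comp["COMPLETE"],
        "complete_pct": percent(comp["COMPLETE"], n),
        "at_least_one_utr": comp["AT_LEAST_ONE_UTR"],
        "homology_evidence": homology,
        "homology_evidence_pct": percent(homology, n),
        # report column flagging possible processed pseudogenes: single-exon
        # truncated models (no UTR, start+stop only); no calls are made
        "single_exon_partial": sum(
            1
            for c in cands
            if len(c.model.representative.exons) == 1
            and classify_completeness(c) is CompletenessClass.PARTIAL
        ),
    }


def exon_intron_stats(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-seq_id exon/intron accounting over representative transcripts.

    For single-transcript genes the identity introns = exons - genes holds per
    group.  Mean exons per gene is reported to one decimal.
    """
    rows = []
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_id, group in sorted(by_seq.items()):
        exon_lengths: list[int] = []
        intron_lengths: list[int] = []
        gene_lengths: list[int] = []
        exon_counts: list[int] = []
        for g in group:
            rep = g.representative
            exon_counts.append(len(rep.exons))
            exon_lengths.extend(e.length for e in rep.exons)
            intron_lengths.extend(i.length for i in rep.introns)
            gene_lengths.append(g.span.length)
        rows.append(
            {
                "seq_id": seq_id,
                "genes": len(group),
                "exons": sum(exon_counts),
                "introns": sum(c - 1 for c in exon_counts),
                "max_exons_per_gene": max(exon_counts),
                "mean_exons_per_gene": round1(sum(exon_counts) / len(group)),
                "shortest_exon": min(exon_lengths),
                "longest_exon": max(exon_lengths),
                "total_exon_length": sum(exon_lengths),
                "shortest_intron": min(intron_lengths) if intron_lengths else 0,
                "longest_intron": max(intron_lengths) if intron_lengths else 0,
                "total_intron_length": sum(intron_lengths),
                "shortest_gene": min(gene_lengths),
                "longest_gene": max(gene_lengths),
                "total_gene_length": sum(gene_lengths),
            }
        )
    return pd.DataFrame(rows)


def write_verdicts(verdicts: Sequence[FilterVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tc1_no_overlap\tc2_length\tc3_score\tc4_support\t"
                 "c5_distance_strand\tpassed\n")
        for v in verdicts:
            fh.write(
                "\t".join(
                    [
                        v.candidate_id,
                        *(
                            str(int(b))
                            for b in (
                                v.c1_no_overlap,
                                v.c2_length,
                                v.c3_score,
                                v.c4_support,
                                v.c5_distance_strand,
                                v.passed,
                            )
                        ),
                    ]
                )
                + "\n"
            )
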