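"""Annotation updates driven by overlap calls, and splice-event comparison.

Evidence alignments modify the annotation in three ways: merging genes that a
single transcript bridges, adding exons the evidence supports inside a gene
body, and extending gene ends with UTR exons.  Updates are applied once —
re-applying the same evidence to the updated gene yields nothing new — and the
comparison is run in two rounds, the second acting as a fixed-point check.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment import TranscriptAlignment
from .model import (
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    Transcript,
    percent,
    validate_model,
)
from .overlap import OverlapCategory


class UpdateKind(enum.Enum):
    MERGE = "MERGE"
    NEW_EXON = "NEW_EXON"
    NEW_UTR5 = "NEW_UTR5"
    NEW_UTR3 = "NEW_UTR3"
    EXTENDED_SPAN = "EXTENDED_SPAN"
    NEW_TRANSCRIPT = "NEW_TRANSCRIPT"


@dataclass(frozen=True)
class UpdateRecord:
    gene_id: str
    update_kind: UpdateKind
    evidence_query_id: str
    before_span: GenomicInterval
    after_span: GenomicInterval

    def __post_init__(self) -> None:
        if self.update_kind in (UpdateKind.NEW_UTR5, UpdateKind.NEW_UTR3, UpdateKind.EXTENDED_SPAN):
            if not self.after_span.contains(self.before_span):
                raise ValueError(
                    f"{self.update_kind.value} record for {self.gene_id}: after_span "
                    "must cover before_span"
                )


class SpliceEventType(enum.Enum):
    RETAINED_INTRON = "RETAINED_INTRON"
    SKIPPED_EXON = "SKIPPED_EXON"
    ALT_ACCEPTOR = "ALT_ACCEPTOR"
    ALT_DONOR = "ALT_DONOR"
    ALT_EXON = "ALT_EXON"
    ENDS_IN_INTRON = "ENDS_IN_INTRON"
    STARTS_IN_INTRON = "STARTS_IN_INTRON"


# ---------------------------------------------------------------------------
# Gene merging
# ---------------------------------------------------------------------------


def merge_genes(
    genes: Sequence[GeneModel], evidence: TranscriptAlignment
) -> GeneModel:
    """Merge two or more genes bridged by one evidence alignment.

    The merged identifier joins the input identifiers with "_" in genomic
    order; the merged span is the envelope of the inputs and the evidence.
    All transcripts are carried over, plus one transcript derived from the
    evidence blocks.
    """
    if len(genes) < 2:
        raise ValueError("merge_genes needs at least 2 genes")
    seq_ids = {g.seq_id for g in genes}
    if len(seq_ids) > 1:
        raise ValueError(f"cannot merge genes on different seq_ids: {sorted(seq_ids)}")
    strands = {g.strand for g in genes}
    if len(strands - {"."}) > 1:
        raise ValueError("cannot merge genes on opposite strands")
    for g in genes:
        if not evidence.span.overlaps(g.span):
            raise ValueError(f"evidence {evidence.query_id} does not overlap {g.gene_id}")
    ordered = sorted(genes, key=lambda g: (g.span.start, g.span.end))
    merged_id = "_".join(g.gene_id for g in ordered)
    strand = next(iter(strands - {"."}), ordered[0].strand)
    ev_tx = Transcript(
        f"{merged_id}.{evidence.query_id}",
        tuple(
            GenomicInterval(b.seq_id, b.start, b.end, strand) for b in evidence.blocks
        ),
    )
    transcripts = tuple(t for g in ordered for t in g.transcripts) + (ev_tx,)
    return GeneModel.from_transcripts(merged_id, transcripts, ordered[0].annotation_status)


# ---------------------------------------------------------------------------
# Per-gene structural updates
# ---------------------------------------------------------------------------


def _merge_segments(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(seg: tuple[int, int], covered: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of `seg` not covered by any (merged, sorted) interval."""
    s, e = seg
    out = []
    for cs, ce in covered:
        if ce < s or cs > e:
            continue
        if cs > s:
            out.append((s, cs - 1))
        s = max(s, ce + 1)
        if s > e:
            break
    if s <= e:
        out.append((s, e))
    return out


def apply_update(
    gene: GeneModel,
    t: TranscriptAlignment,
    category: OverlapCategory,
    cfg: PipelineConfig | None = None,
) -> tuple[GeneModel, list[UpdateRecord]]:
    """Fold one overlapping evidence alignment into a gene model.

    Evidence sequence not covered by any existing exon becomes: NEW_EXON
    segments inside the original gene body, or UTR exons beyond the annotated
    5'/3' edge (at most ``max_utr_exons`` per end, nearest first) with a
    single EXTENDED_SPAN record when the span grows.  Updates are gated on a
    reciprocal span-overlap requirement so marginal overlaps do not rewrite a
    gene.  Applying the same evidence twice adds no second record.
    """
    if category in (OverlapCategory.MERGED, OverlapCategory.INTERGENIC):
        raise ValueError(f"apply_update does not handle {category.value} calls")
    cfg = cfg or PipelineConfig()
    gspan, tspan = gene.span, t.span
    ov = gspan.overlap_length(tspan)
    # overlap gate on the shorter span: marginal overlaps (a sliver of either
    # feature) may not rewrite a gene, while clean extensions/containments pass
    if 100.0 * ov / min(tspan.length, gspan.length) < cfg.compare_min_overlap:
        return gene, []

    exon_cover = _merge_segments((e.start, e.end) for e in gene.all_exons)
    uncovered: list[tuple[int, int]] = []
    for b in sorted(t.blocks, key=lambda b: b.start):
        uncovered.extend(_subtract((b.start, b.end), exon_cover))
    uncovered = _merge_segments(uncovered)

    body: list[tuple[int, int]] = []
    left: list[tuple[int, int]] = []  # beyond the lower genomic edge
    right: list[tuple[int, int]] = []  # beyond the upper genomic edge
    for s, e in uncovered:
        if e < gspan.start:
            left.append((s, e))
        elif s > gspan.end:
            right.append((s, e))
        else:
            # split a segment straddling a gene edge
            if s < gspan.start:
                left.append((s, gspan.start - 1))
            if e > gspan.end:
                right.append((gspan.end + 1, e))
            body.append((max(s, gspan.start), min(e, gspan.end)))

    # unstranded evidence inherits the gene's strand for UTR orientation
    strand = gene.strand if gene.strand != "." else "+"
    left = sorted(left, key=lambda se: -se[1])[: cfg.max_utr_exons]  # nearest first
    right = sorted(right)[: cfg.max_utr_exons]
    lower_kind = UpdateKind.NEW_UTR5 if strand == "+" else UpdateKind.NEW_UTR3
    upper_kind = UpdateKind.NEW_UTR3 if strand == "+" else UpdateKind.NEW_UTR5

    new_exons = body + left + right
    if not new_exons:
        return gene, []

    after_span = GenomicInterval(
        gspan.seq_id,
        min([gspan.start] + [s for s, _ in new_exons]),
        max([gspan.end] + [e for _, e in new_exons]),
        gspan.strand,
    )
    records: list[UpdateRecord] = []
    for s, e in body:
        records.append(
            UpdateRecord(gene.gene_id, UpdateKind.NEW_EXON, t.query_id, gspan, after_span)
        )
    for s, e in sorted(left):
        records.append(
            UpdateRecord(gene.gene_id, lower_kind, t.query_id, gspan, after_span)
        )
    for s, e in right:
        records.append(
            UpdateRecord(gene.gene_id, upper_kind, t.query_id, gspan, after_span)
        )
    if after_span.length > gspan.length:
        records.append(
            UpdateRecord(gene.gene_id, UpdateKind.EXTENDED_SPAN, t.query_id, gspan, after_span)
        )

    rep = gene.representative
    add_ivs = tuple(
        GenomicInterval(gspan.seq_id, s, e, rep.strand) for s, e in sorted(new_exons)
    )
    new_rep = Transcript(
        rep.transcript_id,
        tuple(sorted(rep.exons + add_ivs, key=lambda iv: iv.start)),
        rep.utr5
        + tuple(
            GenomicInterval(gspan.seq_id, s, e, rep.strand)
            for s, e in sorted(left if strand == "+" else right)
        ),
        rep.utr3
        + tuple(
            GenomicInterval(gspan.seq_id, s, e, rep.strand)
            for s, e in sorted(right if strand == "+" else left)
        ),
        rep.has_start_codon,
        rep.has_stop_codon,
    )
    updated = GeneModel.from_transcripts(
        gene.gene_id,
        (new_rep,) + gene.transcripts[1:],
        gene.annotation_status,
    )
    violations = validate_model(updated)
    if violations:  # pragma: no cover - guarded by construction
        raise AssertionError(f"update broke gene invariants: {violations}")
    return updated, records


# ---------------------------------------------------------------------------
# Splice-event comparison
# ---------------------------------------------------------------------------


def classify_splice_events(a: Transcript, b: Transcript) -> list[SpliceEventType]:
    """Splice events of transcript `a` relative to transcript `b`.

    Event types are oriented to `a`: RETAINED_INTRON means `a` expresses
    sequence spanning (or as an internal exon inside) an intron of `b`;
    SKIPPED_EXON is the exact mirror, so swapping the arguments swaps the two
    types and leaves the donor/acceptor and terminal-end events fixed.
    Identical (event, feature-pair) combinations are reported once.
    """
    if a.seq_id != b.seq_id or not (
        a.strand == b.strand or "." in (a.strand, b.strand)
    ):
        raise ValueError("transcripts must share seq_id and a compatible strand")
    if not a.span.overlaps(b.span):
        raise ValueError("transcripts do not overlap")
    strand = a.strand if a.strand != "." else b.strand
    events: set[tuple[SpliceEventType, tuple[int, int], tuple[int, int]]] = set()

    a_ex = sorted(((e.start, e.end) for e in a.exons))
    b_ex = sorted(((e.start, e.end) for e in b.exons))
    a_in = [(i.start, i.end) for i in a.introns]
    b_in = [(i.start, i.end) for i in b.introns]
    a_internal = a_ex[1:-1]
    b_internal = b_ex[1:-1]

    def inside(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return y[0] <= x[0] and x[1] <= y[1]

    for intron in b_in:
        for exon in a_ex:
            if inside(intron, exon):
                events.add((SpliceEventType.RETAINED_INTRON, exon, intron))
    for exon in a_internal:
        for intron in b_in:
            if inside(exon, intron):
                events.add((SpliceEventType.RETAINED_INTRON, exon, intron))
    for intron in a_in:
        for exon in b_ex:
            if inside(intron, exon):
                events.add((SpliceEventType.SKIPPED_EXON, intron, exon))
    for exon in b_internal:
        for intron in a_in:
            if inside(exon, intron):
                events.add((SpliceEventType.SKIPPED_EXON, intron, exon))

    # donor/acceptor per strand: on '+' the donor is the intron start
    for ia in a_in:
        for ib in b_in:
            if ia == ib or not (ia[0] <= ib[1] and ib[0] <= ia[1]):
                continue
            if strand == "-":
                donor_a, acceptor_a = ia[1], ia[0]
                donor_b, acceptor_b = ib[1], ib[0]
            else:
                donor_a, acceptor_a = ia[0], ia[1]
                donor_b, acceptor_b = ib[0], ib[1]
            if donor_a == donor_b and acceptor_a != acceptor_b:
                events.add((SpliceEventType.ALT_ACCEPTOR, ia, ib))
            elif acceptor_a == acceptor_b and donor_a != donor_b:
                events.add((SpliceEventType.ALT_DONOR, ia, ib))

    for ea in a_ex:
        for eb in b_ex:
            if ea[0] <= eb[1] and eb[0] <= ea[1]:
                if not ({ea[0], ea[1]} & {eb[0], eb[1]}):
                    events.add((SpliceEventType.ALT_EXON, ea, eb))

    # terminal exon ending inside an intron of b (per strand orientation)
    if strand == "-":
        a5_exon, a3_exon = a_ex[-1], a_ex[0]
        a5_pos, a3_pos = a5_exon[1], a3_exon[0]
    else:
        a5_exon, a3_exon = a_ex[0], a_ex[-1]
        a5_pos, a3_pos = a5_exon[0], a3_exon[1]
    for intron in b_in:
        if intron[0] <= a3_pos <= intron[1]:
            events.add((SpliceEventType.ENDS_IN_INTRON, a3_exon, intron))
        if intron[0] <= a5_pos <= intron[1]:
            events.add((SpliceEventType.STARTS_IN_INTRON, a5_exon, intron))

    order = [e.value for e in SpliceEventType]
    return [
        ev for ev, _, _ in sorted(events, key=lambda x: (order.index(x[0].value), x[1], x[2]))
    ]


# ---------------------------------------------------------------------------
# Update summary
# ---------------------------------------------------------------------------


def summarize_updates(
    records: Sequence[UpdateRecord], total_genes: int, total_novel: int | None = None
) -> dict:
    """Exact tallies over an update-record stream.

    fraction_updated = 100 * distinct updated genes / total annotated genes,
    reported to one decimal.  When the count of accepted novel genes is given,
    the share of new loci relative to the annotation is reported the same way.
    """
    per_kind = {k.value: 0 for k in UpdateKind}
    per_seq: dict[str, dict[str, int]] = {}
    genes: set[str] = set()
    for r in records:
        per_kind[r.update_kind.value] += 1
        seq = per_seq.setdefault(r.after_span.seq_id, {k.value: 0 for k in UpdateKind})
        seq[r.update_kind.value] += 1
        genes.add(r.gene_id)
    out = {
        "counts_per_kind": per_kind,
        "counts_per_seq_id": per_seq,
        "distinct_genes_updated": len(genes),
        "total_genes": total_genes,
        "fraction_updated_pct": percent(len(genes), total_genes),
    }
    if total_novel is not None:
        out["novel_genes"] = total_novel
        out["new_information_pct"] = percent(total_novel, total_genes)
    return out


def two_round_compare(
    genes: Sequence[GeneModel],
    evidence_calls: Sequence[tuple[TranscriptAlignment, "OverlapCall"]],
    cfg: PipelineConfig | None = None,
) -> tuple[list[GeneModel], list[UpdateRecord], list[UpdateRecord]]:
    """Run the annotation comparison twice, rebuilding between rounds.

    The first round applies every single-gene overlap call; the second re-runs
    the same evidence against the rebuilt annotation and should be a no-op (a
    fixed point) — its records are returned for the caller to assert on.
    """
    cfg = cfg or PipelineConfig()

    def one_round(models: list[GeneModel]) -> tuple[list[GeneModel], list[UpdateRecord]]:
        by_id = {g.gene_id: g for g in models}
        recs: list[UpdateRecord] = []
        for aln, call in evidence_calls:
            if call.category in (OverlapCategory.MERGED, OverlapCategory.INTERGENIC):
                continue
            gid = call.gene_ids[0]
            if gid not in by_id:
                continue
            updated, r = apply_update(by_id[gid], aln, call.category, cfg)
            by_id[gid] = updated
            recs.extend(r)
        return [by_id[g.gene_id] for g in models if g.gene_id in by_id], recs

    round1_models, round1_records = one_round(list(genes))
    round2_models, round2_records = one_round(round1_models)
    return round2_models, round1_records, round2_records


def write_update_records(records: Sequence[UpdateRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tupdate_kind\tevidence_query_id\tbefore\tafter\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.update_kind.value}\t{r.evidence_query_id}\t"
                f"{r.before_span.seq_id}:{r.before_span.start}-{r.before_span.end}\t"
                f"{r.after_span.seq_id}:{r.after_span.start}-{r.after_span.end}\n"
            )


def summary_to_frame(summary: dict) -> pd.DataFrame:
    rows = [
        {"seq_id": seq, **kinds} for seq, kinds in sorted(summary["counts_per_seq_id"].items())
    ]
    return pd.DataFrame(rows)
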