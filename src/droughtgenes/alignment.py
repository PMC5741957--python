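"""HSP chaining, mapping-validity thresholds and genic/intergenic partition.

Expressed-sequence evidence reaches the genome as local alignment blocks
(HSPs).  Blocks from one query are chained greedily left-to-right on the
genome; a chain is closed as soon as admitting the next block would push the
chain's genomic span past ``max_chain_span`` (2 kb by default), which keeps a
chain the size of a plausible transcribed locus.  Assembled transcript
alignments are only considered valid evidence at >=95% identity and >=90%
query coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import GeneModel, GenomicInterval, PipelineConfig, strands_compatible


@dataclass(frozen=True)
class Hsp:
    """A single high-scoring segment pair between a query and the genome."""

    query_id: str
    target: GenomicInterval
    percent_identity: float
    aligned_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if self.aligned_length < 1:
            raise ValueError(f"aligned_length must be >= 1, got {self.aligned_length}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class HspChain:
    query_id: str
    members: tuple[Hsp, ...]
    span: GenomicInterval
    weighted_identity: float  # length-weighted mean identity, %
    coverage: float  # % of query length covered, capped at 100


@dataclass(frozen=True)
class TranscriptAlignment:
    """An assembled, exon-like alignment of one expressed sequence."""

    query_id: str
    blocks: tuple[GenomicInterval, ...]
    percent_identity: float
    coverage: float
    valid: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError(f"alignment {self.query_id}: no blocks")
        bl = sorted(self.blocks, key=lambda b: b.start)
        for left, right in zip(bl, bl[1:]):
            if right.start <= left.end:
                raise ValueError(f"alignment {self.query_id}: overlapping blocks")

    @property
    def seq_id(self) -> str:
        return self.blocks[0].seq_id

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id,
            min(b.start for b in self.blocks),
            max(b.end for b in self.blocks),
            self.strand,
        )


def chain_hsps(
    hsps: Sequence[Hsp], query_length: int, cfg: PipelineConfig
) -> list[HspChain]:
    """Chain one query's HSPs greedily along the genome.

    HSPs below ``min_identity_map`` (inclusive keep at the threshold) or above
    ``evalue_map`` are dropped first.  Surviving HSPs are grouped by
    (seq_id, strand), sorted by target start and chained left to right; a new
    chain opens whenever extending the current one would exceed
    ``max_chain_span``.
    """
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    qids = {h.query_id for h in hsps}
    if len(qids) > 1:
        raise ValueError(f"chain_hsps expects a single query, got {sorted(qids)}")
    keep = [
        h
        for h in hsps
        if h.percent_identity >= cfg.min_identity_map and h.e_value <= cfg.evalue_map
    ]
    chains: list[HspChain] = []
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in keep:
        groups.setdefault((h.target.seq_id, h.target.strand), []).append(h)
    for (seq_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.target.start, h.target.end))
        current: list[Hsp] = []
        for h in members:
            if not current:
                current = [h]
                continue
            lo = min(current[0].target.start, h.target.start)
            hi = max(max(m.target.end for m in current), h.target.end)
            if hi - lo + 1 <= cfg.max_chain_span:
                current.append(h)
            else:
                chains.append(_finish_chain(current, query_length))
                current = [h]
        if current:
            chains.append(_finish_chain(current, query_length))
    return chains


def _finish_chain(members: list[Hsp], query_length: int) -> HspChain:
    seq_id = members[0].target.seq_id
    strand = members[0].target.strand
    span = GenomicInterval(
        seq_id,
        min(m.target.start for m in members),
        max(m.target.end for m in members),
        strand,
    )
    total = sum(m.aligned_length for m in members)
    wid = sum(m.percent_identity * m.aligned_length for m in members) / total
    coverage = 100.0 * min(total, query_length) / query_length
    return HspChain(members[0].query_id, tuple(members), span, wid, coverage)


def validate_alignment(
    aln: TranscriptAlignment, cfg: PipelineConfig
) -> TranscriptAlignment:
    """Return a copy with the validity flag set (thresholds applied as >=)."""
    ok = (
        aln.percent_identity >= cfg.pasa_min_identity
        and aln.coverage >= cfg.pasa_min_coverage
    )
    return replace(aln, valid=ok)


class GeneIndex:
    """Interval-tree index over gene spans, per seq_id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.genes = list(genes)
        for g in self.genes:
            tree = self._trees.setdefault(g.seq_id, IntervalTree())
            # half-open internally; +1 converts the closed end
            tree.addi(g.span.start, g.span.end + 1, g)

    def overlapping(
        self, iv: GenomicInterval, respect_strand: bool = True
    ) -> list[GeneModel]:
        tree = self._trees.get(iv.seq_id)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end + 1)]
        if respect_strand:
            hits = [g for g in hits if strands_compatible(g.strand, iv.strand)]
        return sorted(hits, key=lambda g: (g.span.start, g.span.end, g.gene_id))


def partition_by_locus(
    alignments: Sequence[TranscriptAlignment], genes: Sequence[GeneModel]
) -> tuple[list[TranscriptAlignment], list[TranscriptAlignment]]:
    """Split alignments into genic and intergenic evidence.

    An alignment is genic iff its span shares at least one base with at least
    one gene span on a compatible strand.  Every input lands in exactly one
    partition.
    """
    index = GeneIndex(genes)
    genic, intergenic = [], []
    for aln in alignments:
        (genic if index.overlapping(aln.span) else intergenic).append(aln)
    return genic, intergenic


# ---------------------------------------------------------------------------
# Tabular I/O (BLAST outfmt-6-like HSP table; PSL-like block table)
# ---------------------------------------------------------------------------

HSP_COLUMNS = (
    "query_id",
    "seq_id",
    "start",
    "end",
    "strand",
    "identity",
    "aligned_length",
    "e_value",
    "bit_score",
)


def read_hsp_table(path: str | Path) -> list[Hsp]:
    """Tab-separated HSP dialect: see HSP_COLUMNS (header row optional)."""
    out: list[Hsp] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id\t"):
                continue
            q, seq_id, start, end, strand, ident, alen, ev, bs = line.split("\t")
            out.append(
                Hsp(
                    q,
                    GenomicInterval(seq_id, int(start), int(end), strand),
                    float(ident),
                    int(alen),
                    float(ev),
                    float(bs),
                )
            )
    return out


def write_alignment_table(
    alignments: Sequence[TranscriptAlignment], path: str | Path
) -> None:
    """PSL-like block table: one row per alignment, comma-joined blocks."""
    with open(path, "w") as fh:
        fh.write("query_id\tseq_id\tstrand\tblocks\tidentity\tcoverage\tvalid\n")
        for a in alignments:
            blocks = ",".join(f"{b.start}-{b.end}" for b in a.blocks)
            fh.write(
                f"{a.query_id}\t{a.seq_id}\t{a.strand}\t{blocks}\t"
                f"{a.percent_identity:g}\t{a.coverage:g}\t{int(a.valid)}\n"
            )


def read_alignment_table(path: str | Path) -> list[TranscriptAlignment]:
    out: list[TranscriptAlignment] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("query_id\t"):
                continue
            q, seq_id, strand, blocks, ident, cov, valid = line.split("\t")
            ivs = tuple(
                GenomicInterval(seq_id, int(b.split("-")[0]), int(b.split("-")[1]), strand)
                for b in blocks.split(",")
            )
            out.append(
                TranscriptAlignment(q, ivs, float(ident), float(cov), valid == "1")
            )
    return out
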