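"""Gene–QTL co-localization by coordinate overlap and by filtered alignment hits.

A candidate gene is co-localized with a QTL when their intervals share at
least one base on the same reference sequence; QTLs are unstranded so strand
is ignored.  An alignment-based route keeps, per gene, the best hit (lowest
e-value, ties broken by bit score) passing stringent e-value/identity cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .alignment import Hsp
from .model import GeneModel, GenomicInterval, PipelineConfig, percent, round1


@dataclass(frozen=True)
class Qtl:
    qtl_id: str
    trait: str
    region: GenomicInterval


@dataclass(frozen=True)
class QtlAssociation:
    qtl_id: str
    trait: str
    gene_ids: tuple[str, ...]
    association_mode: str  # coordinate | alignment

    @property
    def multiplicity(self) -> str:
        return "single_gene" if len(self.gene_ids) == 1 else "multi_gene"


def colocalize(
    genes: Sequence[GeneModel], qtls: Sequence[Qtl]
) -> list[QtlAssociation]:
    """One association per QTL overlapped by >= 1 gene, listing all its genes.

    Genes may appear under several QTLs; strand is ignored.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.seq_id, IntervalTree()).addi(
            g.span.start, g.span.end + 1, g.gene_id
        )
    out = []
    for q in qtls:
        tree = trees.get(q.region.seq_id)
        if tree is None:
            continue
        hits = sorted({h.data for h in tree.overlap(q.region.start, q.region.end + 1)})
        if hits:
            out.append(QtlAssociation(q.qtl_id, q.trait, tuple(hits), "coordinate"))
    return out


def filter_qtl_hits(
    hits: Sequence[Hsp], cfg: PipelineConfig | None = None
) -> list[Hsp]:
    """Best hit per query passing e-value < ceiling and identity > cutoff.

    "Best" is the lowest e-value, ties broken by the highest bit score.
    """
    cfg = cfg or PipelineConfig()
    best: dict[str, Hsp] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bit_score) < (cur.e_value, -cur.bit_score):
            best[h.query_id] = h
    return [
        h
        for _, h in sorted(best.items())
        if h.e_value < cfg.qtl_hit_max_evalue
        and h.percent_identity > cfg.qtl_hit_min_identity
    ]


def summarize_associations(
    assocs: Sequence[QtlAssociation], total_input_genes: int
) -> dict:
    """Per-trait tallies and the headline co-localization percentage.

    The headline field is rounded to the nearest integer; the detail field to
    one decimal.
    """
    per_trait: dict[str, dict] = {}
    colocalized: set[str] = set()
    for a in assocs:
        row = per_trait.setdefault(
            a.trait, {"qtls": 0, "genes": set(), "single_gene": 0, "multi_gene": 0}
        )
        row["qtls"] += 1
        row["genes"].update(a.gene_ids)
        row[a.multiplicity] += 1
        colocalized.update(a.gene_ids)
    trait_table = {
        trait: {
            "qtls": row["qtls"],
            "genes": len(row["genes"]),
            "single_gene": row["single_gene"],
            "multi_gene": row["multi_gene"],
        }
        for trait, row in sorted(per_trait.items())
    }
    return {
        "per_trait": trait_table,
        "associations": len(assocs),
        "single_gene_associations": sum(
            1 for a in assocs if a.multiplicity == "single_gene"
        ),
        "multi_gene_associations": sum(
            1 for a in assocs if a.multiplicity == "multi_gene"
        ),
        "colocalized_genes": len(colocalized),
        "total_input_genes": total_input_genes,
        "colocalized_pct_headline": int(percent(len(colocalized), total_input_genes, 0)),
        "colocalized_pct": percent(len(colocalized), total_input_genes),
    }


# ---------------------------------------------------------------------------
# BED / tabular I/O
# ---------------------------------------------------------------------------


def read_qtl_bed(path: str | Path) -> list[Qtl]:
    """BED (0-based half-open) QTLs; the name field holds ``qtl_id;trait``.

    Coordinates are converted to the package's 1-based closed convention at
    this boundary.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            seq_id, start0, end0 = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{seq_id}:{start0}-{end0}"
            qtl_id, _, trait = name.partition(";")
            out.append(
                Qtl(qtl_id, trait or "unknown", GenomicInterval(seq_id, start0 + 1, end0))
            )
    return out


def write_qtl_bed(qtls: Sequence[Qtl], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(
                f"{q.region.seq_id}\t{q.region.start - 1}\t{q.region.end}\t"
                f"{q.qtl_id};{q.trait}\n"
            )


def write_associations(assocs: Sequence[QtlAssociation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("qtl_id\ttrait\tmode\tmultiplicity\tgene_ids\n")
        for a in assocs:
            fh.write(
                f"{a.qtl_id}\t{a.trait}\t{a.association_mode}\t{a.multiplicity}\t"
                f"{','.join(a.gene_ids)}\n"
            )
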