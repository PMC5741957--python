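"""Overlap taxonomy, EST-cluster drought classes and drought gene labels.

A transcript alignment laid against an existing gene model falls into one of
nine span-level overlap categories, determined by how its 5' and 3' edges
relate to the gene's edges (extending beyond, coinciding, or lying inside),
with 5'/3' read in the gene's strand orientation.  Alignments touching two or
more genes are merge evidence; alignments touching none are intergenic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alignment import GeneIndex, TranscriptAlignment
from .model import GeneModel, GenomicInterval, PipelineConfig, strands_compatible


class OverlapCategory(enum.Enum):
    PERFECT = "PERFECT"                  # both edges coincide
    EXT_BOTH = "EXT_BOTH"                # extends beyond both edges
    EXT_5_SHARE_3 = "EXT_5_SHARE_3"      # extends 5', coincides at 3'
    EXT_3_SHARE_5 = "EXT_3_SHARE_5"      # coincides at 5', extends 3'
    PARTIAL_3_EXT_5 = "PARTIAL_3_EXT_5"  # extends 5', ends inside at 3'
    PARTIAL_5_EXT_3 = "PARTIAL_5_EXT_3"  # starts inside at 5', extends 3'
    SHARE_5_INNER_3 = "SHARE_5_INNER_3"  # coincides at 5', ends inside
    SHARE_3_INNER_5 = "SHARE_3_INNER_5"  # starts inside, coincides at 3'
    INNER = "INNER"                      # fully inside the gene
    MERGED = "MERGED"                    # spans two or more genes
    INTERGENIC = "INTERGENIC"            # shares no base with any gene


# (5'-edge relation, 3'-edge relation) -> category; relations are
# 'ext' (beyond the gene edge), 'eq' (coincides) or 'in' (inside the gene).
_DECISION_TABLE: dict[tuple[str, str], OverlapCategory] = {
    ("ext", "ext"): OverlapCategory.EXT_BOTH,
    ("ext", "eq"): OverlapCategory.EXT_5_SHARE_3,
    ("eq", "ext"): OverlapCategory.EXT_3_SHARE_5,
    ("eq", "eq"): OverlapCategory.PERFECT,
    ("ext", "in"): OverlapCategory.PARTIAL_3_EXT_5,
    ("in", "ext"): OverlapCategory.PARTIAL_5_EXT_3,
    ("eq", "in"): OverlapCategory.SHARE_5_INNER_3,
    ("in", "eq"): OverlapCategory.SHARE_3_INNER_5,
    ("in", "in"): OverlapCategory.INNER,
}


def classify_pair(
    t_span: GenomicInterval, g: GeneModel
) -> OverlapCategory | None:
    """Classify a transcript span against one gene (span-level decision table).

    Returns None when the two intervals share no base.  On the minus strand
    the 5' edge is the higher genomic coordinate.  A single shared base counts
    as overlap.
    """
    gspan = g.span
    if t_span.seq_id != gspan.seq_id:
        raise ValueError(
            f"seq_id mismatch: {t_span.seq_id} vs {gspan.seq_id}"
        )
    if not strands_compatible(t_span.strand, gspan.strand):
        raise ValueError("strands are incompatible")
    if not t_span.overlaps(gspan):
        return None

    def rel(t_coord: int, g_coord: int, outward: int) -> str:
        # outward = +1 when "beyond the edge" means a larger coordinate
        if t_coord == g_coord:
            return "eq"
        return "ext" if (t_coord - g_coord) * outward > 0 else "in"

    if gspan.strand == "-":
        five = rel(t_span.end, gspan.end, +1)
        three = rel(t_span.start, gspan.start, -1)
    else:
        five = rel(t_span.start, gspan.start, -1)
        three = rel(t_span.end, gspan.end, +1)
    return _DECISION_TABLE[(five, three)]


@dataclass(frozen=True)
class OverlapCall:
    """One transcript's verdict: category plus the gene(s) involved."""

    query_id: str
    category: OverlapCategory
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.category is OverlapCategory.MERGED and n < 2:
            raise ValueError("MERGED calls need >= 2 gene ids")
        if self.category is OverlapCategory.INTERGENIC and n != 0:
            raise ValueError("INTERGENIC calls carry no gene ids")
        if self.category not in (OverlapCategory.MERGED, OverlapCategory.INTERGENIC) and n != 1:
            raise ValueError(f"{self.category.value} calls need exactly 1 gene id")


def call_transcript(
    t: TranscriptAlignment, genes: Sequence[GeneModel] | GeneIndex
) -> OverlapCall:
    """Assign a transcript alignment its overlap call against an annotation."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hits = index.overlapping(t.span)
    if not hits:
        return OverlapCall(t.query_id, OverlapCategory.INTERGENIC, ())
    if len(hits) >= 2:
        return OverlapCall(
            t.query_id, OverlapCategory.MERGED, tuple(g.gene_id for g in hits)
        )
    category = classify_pair(t.span, hits[0])
    assert category is not None
    return OverlapCall(t.query_id, category, (hits[0].gene_id,))


# ---------------------------------------------------------------------------
# EST libraries and cluster drought classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstLibrary:
    library_id: str
    drought_stressed: bool
    developmental_stage: str = ""


DROUGHT_CLASSES = ("DREST_ONLY", "MIXED", "NON_DREST")


@dataclass(frozen=True)
class UniGeneCluster:
    """A non-redundant EST cluster with its drought-content class."""

    cluster_id: str
    member_ests: tuple[tuple[str, str], ...]  # (est_id, library_id)
    drought_class: str = "NON_DREST"

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ests", tuple(self.member_ests))
        if self.drought_class not in DROUGHT_CLASSES:
            raise ValueError(f"unknown drought class {self.drought_class!r}")


def classify_cluster(
    cluster: UniGeneCluster, libraries: Mapping[str, EstLibrary]
) -> str:
    """DREST_ONLY if every member EST comes from a drought-stressed library,
    NON_DREST if none does, MIXED otherwise."""
    flags = []
    for est_id, library_id in cluster.member_ests:
        if library_id not in libraries:
            raise KeyError(f"EST {est_id}: unknown library {library_id!r}")
        flags.append(libraries[library_id].drought_stressed)
    if flags and all(flags):
        return "DREST_ONLY"
    if not any(flags):
        return "NON_DREST"
    return "MIXED"


def label_genes_drought(
    calls: Iterable[OverlapCall],
    clusters: Mapping[str, UniGeneCluster],
    cfg: PipelineConfig | None = None,
) -> dict[str, bool]:
    """Label genes drought-responsive from the clusters that overlap them.

    A gene is drought-responsive iff at least one overlapping call's cluster
    is DREST_ONLY (or MIXED, unless restricted via config).  Intergenic calls
    contribute nothing.  Genes touched only by non-drought clusters come back
    False so the caller sees the full universe of overlapped genes.
    """
    allowed = {"DREST_ONLY"}
    if cfg is None or cfg.mixed_clusters_confer_drought:
        allowed.add("MIXED")
    labels: dict[str, bool] = {}
    for call in calls:
        if call.category is OverlapCategory.INTERGENIC:
            continue
        cluster = clusters.get(call.query_id)
        hit = cluster is not None and cluster.drought_class in allowed
        for gid in call.gene_ids:
            labels[gid] = labels.get(gid, False) or hit
    return labels


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_library_table(path: str | Path) -> dict[str, EstLibrary]:
    """Tab-separated (library_id, drought_stressed, stage)."""
    out: dict[str, EstLibrary] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("library_id\t"):
                continue
            lib_id, drought, stage = line.split("\t")
            if lib_id in out:
                raise ValueError(f"duplicate library_id {lib_id!r}")
            out[lib_id] = EstLibrary(lib_id, drought == "1", stage)
    return out


def read_cluster_table(
    path: str | Path, libraries: Mapping[str, EstLibrary]
) -> dict[str, UniGeneCluster]:
    """Tab-separated (cluster_id, est_id, library_id); classes recomputed."""
    members: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("cluster_id\t"):
                continue
            cid, est_id, lib_id = line.split("\t")
            members.setdefault(cid, []).append((est_id, lib_id))
    out = {}
    for cid, ests in members.items():
        cluster = UniGeneCluster(cid, tuple(ests))
        out[cid] = UniGeneCluster(cid, tuple(ests), classify_cluster(cluster, libraries))
    return out


def write_overlap_calls(calls: Sequence[OverlapCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcategory\tgene_ids\n")
        for c in calls:
            fh.write(f"{c.query_id}\t{c.category.value}\t{','.join(c.gene_ids)}\n")
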