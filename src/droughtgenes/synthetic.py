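"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of the real inputs — EST
clusters with per-library drought flags, transcript alignments with planted
overlap classes, treatment x tissue expression designs with planted fold
changes, QTL intervals with planted gene overlaps — on integer-grid
coordinates with a 50 bp minimum feature size.  Every record is traceable to
one truth entry, and the truth is exactly recoverable by the corresponding
analysis stage under noiseless settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import TranscriptAlignment
from .expression import ExpressionMatrix
from .model import GeneModel, GenomicInterval, Transcript
from .overlap import EstLibrary, OverlapCategory, UniGeneCluster
from .enrichment import TermMap
from .qtl import Qtl

MIN_FEATURE = 50  # bp — smallest exon/intron/gap the generators emit


@dataclass
class SyntheticTruth:
    """Ground-truth labels for recovery testing, one entry per planted record."""

    overlap_labels: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    drought_genes: set[str] = field(default_factory=set)
    cluster_classes: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> direction
    enriched_term: str | None = None
    study_genes: set[str] = field(default_factory=set)
    qtl_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    update_counts: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def gen_annotation(
    n_genes: int,
    n_seqids: int = 1,
    mean_gene_length: int = 900,
    mean_gap: int = 500,
    exon_geom_p: float = 0.45,
    seed: int = 0,
) -> tuple[list[GeneModel], SyntheticTruth]:
    """Non-overlapping exon-chain genes laid left to right per seq_id.

    Exon counts are geometric (capped at 6); exons and introns are at least
    MIN_FEATURE long; inter-gene gaps at least 3x MIN_FEATURE so overlap
    categories with extensions have room.  Deterministic under a fixed seed.
    """
    if n_genes < 0 or n_seqids < 1:
        raise ValueError("need n_genes >= 0 and n_seqids >= 1")
    if mean_gene_length < 2 * MIN_FEATURE or mean_gap < 3 * MIN_FEATURE:
        raise ValueError("gene/gap lengths too small for the coordinate grid")
    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    for gi in range(n_genes):
        seq_id = f"chr{gi % n_seqids + 1}"
        gene_id = f"Sg{gi + 1:05d}"
        n_exons = min(6, rng.geometric(exon_geom_p))
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lengths = MIN_FEATURE + rng.integers(
            0, max(1, mean_gene_length // max(1, n_exons)), size=n_exons
        )
        intron_lengths = (
            MIN_FEATURE + rng.integers(0, MIN_FEATURE * 2, size=max(0, n_exons - 1))
        )
        status = ["characterised", "hypothetical", "putatively_uncharacterised", "unknown"][
            int(rng.integers(0, 4))
        ]
        models.append(
            (seq_id, gene_id, strand, exon_lengths, intron_lengths, status)
        )
    out: list[GeneModel] = []
    cursor: dict[str, int] = {}
    rng2 = np.random.default_rng(seed + 1)
    for seq_id, gene_id, strand, exon_lengths, intron_lengths, status in models:
        pos = cursor.get(seq_id, 1) + 3 * MIN_FEATURE + int(rng2.integers(0, mean_gap))
        exons = []
        for i, el in enumerate(exon_lengths):
            exons.append((pos, pos + int(el) - 1))
            pos += int(el)
            if i < len(intron_lengths):
                pos += int(intron_lengths[i])
        cursor[seq_id] = exons[-1][1]
        out.append(
            GeneModel.from_exons(
                gene_id, seq_id, exons, strand, status,
                has_start_codon=True, has_stop_codon=True,
            )
        )
    truth = SyntheticTruth(params={"n_genes": n_genes, "n_seqids": n_seqids, "seed": seed})
    return out, truth


def _neighbour_room(genes: list[GeneModel]) -> dict[str, tuple[int, int]]:
    """Free bases to the previous/next gene span on each side, per gene."""
    room: dict[str, tuple[int, int]] = {}
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_genes in by_seq.values():
        seq_genes.sort(key=lambda g: g.span.start)
        for i, g in enumerate(seq_genes):
            left = (
                g.span.start - seq_genes[i - 1].span.end - 1 if i > 0 else g.span.start - 1
            )
            right = (
                seq_genes[i + 1].span.start - g.span.end - 1
                if i < len(seq_genes) - 1
                else 10 * MIN_FEATURE
            )
            room[g.gene_id] = (left, right)
    return room


# ---------------------------------------------------------------------------
# Overlap-class alignments
# ---------------------------------------------------------------------------

_SINGLE_GENE_CATEGORIES = {
    OverlapCategory.PERFECT: ("eq", "eq"),
    OverlapCategory.EXT_BOTH: ("ext", "ext"),
    OverlapCategory.EXT_5_SHARE_3: ("ext", "eq"),
    OverlapCategory.EXT_3_SHARE_5: ("eq", "ext"),
    OverlapCategory.PARTIAL_3_EXT_5: ("ext", "in"),
    OverlapCategory.PARTIAL_5_EXT_3: ("in", "ext"),
    OverlapCategory.SHARE_5_INNER_3: ("eq", "in"),
    OverlapCategory.SHARE_3_INNER_5: ("in", "eq"),
    OverlapCategory.INNER: ("in", "in"),
}


def gen_alignments(
    annotation: Sequence[GeneModel],
    histogram: dict[OverlapCategory, int],
    seed: int = 0,
) -> tuple[list[TranscriptAlignment], SyntheticTruth]:
    """Alignments whose spans realise the requested overlap categories.

    Single-gene categories are constructed from the decision-table edge
    relations against a randomly chosen gene; MERGED spans bridge two
    same-strand neighbouring genes; INTERGENIC spans sit wholly inside a gap.
    The truth records every planted label.
    """
    genes = sorted(annotation, key=lambda g: (g.seq_id, g.span.start))
    rng = np.random.default_rng(seed)
    room = _neighbour_room(list(genes))
    truth = SyntheticTruth(params={"seed": seed})
    out: list[TranscriptAlignment] = []
    counter = 0

    def emit(span: tuple[str, int, int, str], category: OverlapCategory,
             gene_ids: tuple[str, ...]) -> None:
        nonlocal counter
        counter += 1
        qid = f"Q{counter:05d}.{category.value}"
        seq_id, s, e, strand = span
        n_blocks = int(rng.integers(1, 4))
        length = e - s + 1
        if n_blocks > 1 and length >= n_blocks * 3 + (n_blocks - 1):
            cuts = np.sort(rng.choice(np.arange(1, length - 1), size=2 * (n_blocks - 1), replace=False))
            edges = [s] + [s + int(c) for c in cuts] + [e]
            blocks = []
            ok = True
            for i in range(0, len(edges) - 1, 2):
                bs, be = edges[i], edges[i + 1]
                if be < bs:
                    ok = False
                    break
                blocks.append(GenomicInterval(seq_id, bs, be, strand))
            if not ok or len(blocks) != n_blocks:
                blocks = [GenomicInterval(seq_id, s, e, strand)]
        else:
            blocks = [GenomicInterval(seq_id, s, e, strand)]
        identity = float(96 + 3.5 * rng.random())
        coverage = float(92 + 8 * rng.random())
        out.append(TranscriptAlignment(qid, tuple(blocks), round(identity, 2), round(coverage, 2)))
        truth.overlap_labels[qid] = (category.value, gene_ids)

    merged_pairs = []
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_genes in by_seq.values():
        for a, b in zip(seq_genes, seq_genes[1:]):
            if a.strand == b.strand:
                merged_pairs.append((a, b))

    for category in sorted(histogram, key=lambda c: c.value):
        count = histogram[category]
        if category is OverlapCategory.MERGED:
            if count and not merged_pairs:
                raise ValueError("annotation too small for MERGED requests")
            for _ in range(count):
                a, b = merged_pairs[int(rng.integers(0, len(merged_pairs)))]
                s = a.span.start + int(rng.integers(0, max(1, a.span.length // 2)))
                e = b.span.end - int(rng.integers(0, max(1, b.span.length // 2)))
                emit((a.seq_id, s, e, a.strand), category, (a.gene_id, b.gene_id))
            continue
        if category is OverlapCategory.INTERGENIC:
            for _ in range(count):
                gi = int(rng.integers(0, len(genes)))
                g = genes[gi]
                left, right = room[g.gene_id]
                width = int(rng.integers(MIN_FEATURE, 2 * MIN_FEATURE))
                if right >= width + 2:
                    s = g.span.end + 1 + int(rng.integers(1, right - width))
                elif left >= width + 2:
                    s = g.span.start - 1 - width - int(rng.integers(1, left - width))
                else:
                    continue
                emit((g.seq_id, s, s + width - 1, "."), category, ())
            continue
        five_rel, three_rel = _SINGLE_GENE_CATEGORIES[category]
        for _ in range(count):
            # pick a gene with enough interior and exterior room
            for _attempt in range(50):
                g = genes[int(rng.integers(0, len(genes)))]
                left, right = room[g.gene_id]
                if g.span.length >= 4 * MIN_FEATURE and left >= 3 and right >= 3:
                    break
            gs, ge = g.span.start, g.span.end
            inner = max(1, g.span.length // 5)
            if g.strand == "-":
                hi_rel, lo_rel = five_rel, three_rel
            else:
                lo_rel, hi_rel = five_rel, three_rel
            if lo_rel == "ext":
                s = gs - int(rng.integers(1, min(left, 2 * MIN_FEATURE)))
            elif lo_rel == "eq":
                s = gs
            else:
                s = gs + int(rng.integers(1, inner + 1))
            if hi_rel == "ext":
                e = ge + int(rng.integers(1, min(right, 2 * MIN_FEATURE)))
            elif hi_rel == "eq":
                e = ge
            else:
                e = ge - int(rng.integers(1, inner + 1))
            emit((g.seq_id, s, e, g.strand), category, (g.gene_id,))
    return out, truth


# ---------------------------------------------------------------------------
# Structural-update evidence
# ---------------------------------------------------------------------------


def gen_update_evidence(
    annotation: Sequence[GeneModel],
    n_new_exon: int = 10,
    n_utr5: int = 10,
    n_utr3: int = 10,
    seed: int = 0,
) -> tuple[list[tuple[TranscriptAlignment, GeneModel]], SyntheticTruth]:
    """Evidence alignments planting exactly the requested update events.

    Each alignment reproduces its gene's exon chain and adds either one block
    inside an intron (NEW_EXON) or a short terminal extension beyond the 5'
    or 3' gene edge (NEW_UTR5 / NEW_UTR3, with the accompanying span
    extension).  Each gene carries at most one planted event.
    """
    rng = np.random.default_rng(seed)
    room = _neighbour_room(sorted(annotation, key=lambda g: (g.seq_id, g.span.start)))
    multi = [g for g in annotation if len(g.representative.exons) >= 2
             and min(i.length for i in g.representative.introns) >= MIN_FEATURE]
    any_genes = list(annotation)
    rng.shuffle(multi)
    rng.shuffle(any_genes)
    used: set[str] = set()
    out: list[tuple[TranscriptAlignment, GeneModel]] = []
    truth = SyntheticTruth(params={"seed": seed})
    counts = {"NEW_EXON": 0, "NEW_UTR5": 0, "NEW_UTR3": 0}
    qn = 0

    def exon_blocks(g: GeneModel) -> list[GenomicInterval]:
        return [
            GenomicInterval(e.seq_id, e.start, e.end, e.strand)
            for e in g.representative.exons
        ]

    for g in multi:
        if counts["NEW_EXON"] >= n_new_exon:
            break
        if g.gene_id in used:
            continue
        intron = g.representative.introns[0]
        pad = max(1, (intron.length - MIN_FEATURE // 2) // 2)
        block = GenomicInterval(
            g.seq_id, intron.start + pad, intron.end - pad, g.strand
        )
        if block.start > block.end or block.start <= intron.start or block.end >= intron.end:
            continue
        qn += 1
        blocks = sorted(exon_blocks(g) + [block], key=lambda b: b.start)
        aln = TranscriptAlignment(f"U{qn:05d}.NEW_EXON", tuple(blocks), 98.0, 99.0)
        out.append((aln, g))
        used.add(g.gene_id)
        counts["NEW_EXON"] += 1

    for kind, want in (("NEW_UTR5", n_utr5), ("NEW_UTR3", n_utr3)):
        for g in any_genes:
            if counts[kind] >= want:
                break
            if g.gene_id in used:
                continue
            left, right = room[g.gene_id]
            ext = min(30, g.span.length // 5)
            strand = g.strand
            # the lower genomic edge is the 5' end on '+', the 3' end on '-'
            lower = (kind == "NEW_UTR5") == (strand == "+")
            if lower:
                if left <= ext + 1 or ext < 1:
                    continue
                add = GenomicInterval(g.seq_id, g.span.start - ext, g.span.start - 1, strand)
            else:
                if right <= ext + 1 or ext < 1:
                    continue
                add = GenomicInterval(g.seq_id, g.span.end + 1, g.span.end + ext, strand)
            qn += 1
            blocks = sorted(exon_blocks(g) + [add], key=lambda b: b.start)
            # fuse the added block with the adjacent terminal exon
            fused: list[GenomicInterval] = []
            for b in blocks:
                if fused and b.start <= fused[-1].end + 1:
                    fused[-1] = GenomicInterval(b.seq_id, fused[-1].start, max(b.end, fused[-1].end), b.strand)
                else:
                    fused.append(b)
            aln = TranscriptAlignment(f"U{qn:05d}.{kind}", tuple(fused), 98.0, 99.0)
            out.append((aln, g))
            used.add(g.gene_id)
            counts[kind] += 1

    for kind, want in counts.items():
        truth.update_counts[kind] = want
    return out, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gen_expression(
    n_genes: int = 1000,
    n_per_cell: int = 4,
    de_fraction: float = 0.01,
    log2fc: float = 2.0,
    sigma: float = 0.25,
    tissues: Sequence[str] = ("root", "shoot"),
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    counts: bool = False,
    nb_dispersion: float = 10.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Lognormal abundances with planted up-regulation in the drought arm.

    Per-gene baseline log2 abundance is N(log2(100), 1.5^2); replicate noise
    is N(0, sigma^2) in log2 space; planted genes are shifted by ``log2fc`` in
    every drought sample.  ``de_fraction=0`` yields a null matrix.  With
    ``counts=True`` the lognormal means parameterise a negative-binomial draw
    (gamma-Poisson with shape ``nb_dispersion``), producing an integer count
    matrix for exact-test exercises.
    """
    if not (0 <= de_fraction <= 1):
        raise ValueError("de_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    else:
        gene_ids = list(gene_ids)[:n_genes]
        gene_ids += [f"G{i + 1:05d}" for i in range(len(gene_ids), n_genes)]
    samples = []
    meta_rows = []
    for treatment in ("drought", "control"):
        for tissue in tissues:
            for r in range(1, n_per_cell + 1):
                sid = f"{treatment}_{tissue}_{r}"
                samples.append(sid)
                meta_rows.append({"sample_id": sid, "treatment": treatment, "tissue": tissue})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    base = rng.normal(np.log2(100.0), 1.5, size=n_genes)
    noise = rng.normal(0.0, sigma, size=(n_genes, len(samples)))
    log2_expr = base[:, None] + noise
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    drought_cols = np.array([m["treatment"] == "drought" for m in meta_rows])
    log2_expr[np.ix_(de_idx, np.where(drought_cols)[0])] += log2fc
    expr = np.power(2.0, log2_expr)
    if counts:
        lam = rng.gamma(nb_dispersion, expr / nb_dispersion)
        expr = rng.poisson(lam).astype(float)
    values = pd.DataFrame(expr, index=gene_ids, columns=samples).round(4)
    truth = SyntheticTruth(
        de_genes={gene_ids[i]: "up" for i in sorted(de_idx)},
        params={
            "n_genes": n_genes, "n_per_cell": n_per_cell, "de_fraction": de_fraction,
            "log2fc": log2fc, "sigma": sigma, "seed": seed,
        },
    )
    return ExpressionMatrix(values, meta), truth


# ---------------------------------------------------------------------------
# Auxiliary inputs: libraries/clusters, term map, QTLs
# ---------------------------------------------------------------------------


def gen_aux(
    annotation: Sequence[GeneModel],
    alignment_truth: SyntheticTruth,
    n_libraries: int = 12,
    drought_gene_fraction: float = 0.3,
    n_terms: int = 15,
    n_qtls: int = 5,
    seed: int = 0,
) -> tuple[
    dict[str, EstLibrary], dict[str, UniGeneCluster], TermMap, list[Qtl], SyntheticTruth
]:
    """EST libraries and clusters, a term map with one planted enriched term,
    and QTL intervals with planted gene overlaps.

    Clusters are keyed by alignment query_id: queries overlapping a planted
    drought gene get DREST_ONLY or MIXED clusters, all others NON_DREST, so
    the drought gene labels are exactly recoverable.  The planted term
    annotates precisely the drought study set and must rank first in the
    enrichment.  QTLs cover runs of consecutive genes.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(params={"seed": seed})
    genes = sorted(annotation, key=lambda g: (g.seq_id, g.span.start))
    gene_ids = [g.gene_id for g in genes]

    libraries = {}
    for i in range(n_libraries):
        lid = f"LIB{i + 1:03d}"
        libraries[lid] = EstLibrary(
            lid, drought_stressed=(i < n_libraries // 2),
            developmental_stage="post-flowering" if i % 2 else "pre-flowering",
        )
    drought_libs = [l for l in libraries.values() if l.drought_stressed]
    control_libs = [l for l in libraries.values() if not l.drought_stressed]

    # plant drought genes among those overlapped by single-gene calls
    overlapped = sorted(
        {
            gid
            for cat, gids in alignment_truth.overlap_labels.values()
            for gid in gids
            if cat not in ("MERGED", "INTERGENIC")
        }
    )
    n_drought = max(1, int(round(drought_gene_fraction * len(overlapped)))) if overlapped else 0
    drought_genes = set(
        rng.choice(overlapped, size=n_drought, replace=False)
    ) if n_drought else set()
    truth.drought_genes = drought_genes

    clusters: dict[str, UniGeneCluster] = {}
    est_n = 0
    for qid, (cat, gids) in sorted(alignment_truth.overlap_labels.items()):
        if cat == "INTERGENIC":
            continue
        is_drought = bool(set(gids) & drought_genes) and cat != "MERGED"
        if is_drought:
            cls = "DREST_ONLY" if rng.random() < 0.6 else "MIXED"
        else:
            cls = "NON_DREST"
        n_members = int(rng.integers(2, 5))
        members = []
        for j in range(n_members):
            est_n += 1
            if cls == "DREST_ONLY":
                lib = drought_libs[int(rng.integers(0, len(drought_libs)))]
            elif cls == "NON_DREST":
                lib = control_libs[int(rng.integers(0, len(control_libs)))]
            else:
                # a MIXED cluster carries one drought EST and >= 1 control EST
                pool = drought_libs if j == 0 else control_libs
                lib = pool[int(rng.integers(0, len(pool)))]
            members.append((f"EST{est_n:06d}", lib.library_id))
        clusters[qid] = UniGeneCluster(f"cluster_{qid}", tuple(members), cls)
        truth.cluster_classes[qid] = cls

    # term map: planted term annotates exactly the drought study set
    study = set(drought_genes) or set(gene_ids[:3])
    term_to_genes: dict[str, set[str]] = {}
    if gene_ids:
        term_to_genes["TERM:PLANTED"] = set(study)
        for i in range(n_terms):
            size = int(rng.integers(3, max(4, len(gene_ids) // 3)))
            term_to_genes[f"TERM:{i + 1:04d}"] = set(
                rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
            )
        truth.enriched_term = "TERM:PLANTED"
    parents = {t: {"TERM:ROOT"} for t in list(term_to_genes)[1 : min(n_terms, 5) + 1]}
    tm = TermMap(term_to_genes, parents, background=set(gene_ids))
    truth.study_genes = study

    traits = ("stay-green", "grain yield", "nodal root angle", "flowering time", "seed dormancy")
    qtls: list[Qtl] = []
    for i in range(n_qtls):
        if not genes:
            break
        start_idx = int(rng.integers(0, len(genes)))
        width = int(rng.integers(1, 5))
        run = [g for g in genes[start_idx : start_idx + width] if g.seq_id == genes[start_idx].seq_id]
        region = GenomicInterval(
            run[0].seq_id,
            max(1, run[0].span.start - int(rng.integers(0, MIN_FEATURE))),
            run[-1].span.end + int(rng.integers(0, MIN_FEATURE)),
        )
        qid = f"qDT{i + 1}"
        qtls.append(Qtl(qid, traits[i % len(traits)], region))
        covered = tuple(
            sorted(g.gene_id for g in genes if g.span.overlaps(region))
        )
        truth.qtl_genes[qid] = covered
    return libraries, clusters, tm, qtls, truth


# ---------------------------------------------------------------------------
# Ortholog table
# ---------------------------------------------------------------------------


def gen_orthologs(
    gene_ids: Sequence[str],
    species: Sequence[str] = ("maize", "rice", "arabidopsis"),
    retained_fraction: float = 0.6,
    seed: int = 0,
):
    """Random ortholog records; roughly `retained_fraction` pass screening."""
    from .enrichment import OrthologRecord

    rng = np.random.default_rng(seed)
    out = []
    for gid in gene_ids:
        for sp in species:
            if rng.random() < 0.8:
                retained = rng.random() < retained_fraction
                ident = float(55 + 40 * rng.random()) if retained else float(20 + 29 * rng.random())
                conf = "high" if retained else ("high" if rng.random() < 0.3 else "low")
                if not retained and conf == "high":
                    ident = min(ident, 49.0)
                htype = ("one2one", "one2many", "many2many")[int(rng.integers(0, 3))]
                out.append(
                    OrthologRecord(gid, f"{sp[:2]}_{gid}", sp, round(ident, 1), conf, htype)
                )
    return out


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Flat tab-separated truth dump for external harnesses."""
    with open(path, "w") as fh:
        fh.write("kind\tkey\tvalue\n")
        for qid, (cat, gids) in sorted(truth.overlap_labels.items()):
            fh.write(f"overlap\t{qid}\t{cat}:{','.join(gids)}\n")
        for gid in sorted(truth.drought_genes):
            fh.write(f"drought_gene\t{gid}\t1\n")
        for gid, direction in sorted(truth.de_genes.items()):
            fh.write(f"de_gene\t{gid}\t{direction}\n")
        if truth.enriched_term:
            fh.write(f"enriched_term\t{truth.enriched_term}\t1\n")
        for qid, gids in sorted(truth.qtl_genes.items()):
            fh.write(f"qtl\t{qid}\t{','.join(gids)}\n")
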