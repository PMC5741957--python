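"""Fisher's-exact term enrichment (SEA-style) and ortholog-table screening.

Term enrichment tests each term's 2x2 table (study vs background, annotated
vs not) with a two-sided Fisher's exact test and adjusts across tested terms
with Benjamini–Hochberg.  Ortholog screening keeps high-confidence records
above an identity cutoff; shared-set accounting partitions source genes into
exclusive Venn regions over the species they hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .expression import bh_fdr
from .model import PipelineConfig


@dataclass
class TermMap:
    """term -> genes annotation with optional parent edges and a background."""

    term_to_genes: dict[str, set[str]]
    parents: dict[str, set[str]] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set().union(*self.term_to_genes.values()) if self.term_to_genes else set()
        missing = set().union(*self.term_to_genes.values()) - self.background if self.term_to_genes else set()
        if missing:
            raise ValueError(
                f"annotated genes missing from background: {sorted(missing)[:5]}"
            )

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.term_to_genes)
        for child, parents in self.parents.items():
            for p in parents:
                g.add_edge(child, p)
        return g


def propagate_terms(tm: TermMap) -> TermMap:
    """Annotate every gene to all ancestors of its terms (transitive closure).

    Idempotent; a cycle in the parent graph is an error naming the cycle.
    """
    g = tm._graph()
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"parent graph has a cycle: {cycle}")
    closed: dict[str, set[str]] = {t: set(gs) for t, gs in tm.term_to_genes.items()}
    for term in tm.term_to_genes:
        for ancestor in nx.descendants(g, term):  # edges point child -> parent
            closed.setdefault(ancestor, set()).update(tm.term_to_genes[term])
    return TermMap(closed, dict(tm.parents), set(tm.background))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study genes with the term
    n: int  # study size
    K: int  # background genes with the term
    N: int  # background size
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("k cannot exceed min(n, K)")


def sea_enrichment(
    study: Iterable[str],
    tm: TermMap,
    cfg: PipelineConfig | None = None,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Per-term Fisher's exact test of a study set against the background.

    Terms annotating no background gene are skipped.  Results are sorted by
    (q, p, term_id); significance is q < ``fdr_alpha``.
    """
    cfg = cfg or PipelineConfig()
    study_set = set(study)
    extra = study_set - tm.background
    if extra:
        raise ValueError(f"study genes outside background: {sorted(extra)[:5]}")
    n = len(study_set)
    N = len(tm.background)
    rows = []
    for term_id in sorted(tm.term_to_genes):
        genes = tm.term_to_genes[term_id] & tm.background
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & study_set)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        p = stats.fisher_exact(table, alternative=alternative)[1]
        rows.append((term_id, k, K, p))
    qs = bh_fdr([p for *_, p in rows])
    results = [
        EnrichmentResult(term_id, k, n, K, N, p, q)
        for (term_id, k, K, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


# ---------------------------------------------------------------------------
# Ortholog screening
# ---------------------------------------------------------------------------

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")


@dataclass(frozen=True)
class OrthologRecord:
    source_gene: str
    target_gene: str
    species: str
    percent_identity: float
    confidence: str  # high | low
    homology_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity out of [0,100]")
        if self.confidence not in ("high", "low"):
            raise ValueError(f"confidence must be high/low, got {self.confidence!r}")
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValueError(f"unknown homology type {self.homology_type!r}")


def screen_orthologs(
    records: Sequence[OrthologRecord],
    cfg: PipelineConfig | None = None,
    min_identity: float | None = None,
) -> list[OrthologRecord]:
    """Keep records with identity strictly above the cutoff and high confidence.

    All homology types are admissible.  ``min_identity`` overrides the config
    cutoff (e.g. 90 for the stringent cross-species comparison).
    """
    cfg = cfg or PipelineConfig()
    cutoff = cfg.ortholog_min_identity if min_identity is None else min_identity
    return [
        r
        for r in records
        if r.percent_identity > cutoff and r.confidence == "high"
    ]


def shared_ortholog_sets(
    records: Sequence[OrthologRecord],
) -> dict[frozenset[str], int]:
    """Exclusive Venn-region counts of source genes over species subsets.

    A source gene falls in exactly the region of the species set it has
    retained orthologs in; regions therefore partition the represented genes.
    """
    species_by_gene: dict[str, set[str]] = {}
    for r in records:
        species_by_gene.setdefault(r.source_gene, set()).add(r.species)
    regions: dict[frozenset[str], int] = {}
    for gene, species in species_by_gene.items():
        key = frozenset(species)
        regions[key] = regions.get(key, 0) + 1
    return regions


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_term_map(
    annotation_path: str | Path, parent_path: str | Path | None = None
) -> TermMap:
    """2-column (term_id, gene_id) annotation plus optional (term, parent) edges."""
    term_to_genes: dict[str, set[str]] = {}
    with open(annotation_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("term_id\t"):
                continue
            term, gene = line.split("\t")
            term_to_genes.setdefault(term, set()).add(gene)
    parents: dict[str, set[str]] = {}
    if parent_path is not None:
        with open(parent_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("term_id\t"):
                    continue
                term, parent = line.split("\t")
                parents.setdefault(term, set()).add(parent)
    return TermMap(term_to_genes, parents)


def read_ortholog_table(path: str | Path) -> list[OrthologRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("source_gene\t"):
                continue
            src, tgt, sp, ident, conf, htype = line.split("\t")
            out.append(OrthologRecord(src, tgt, sp, float(ident), conf, htype))
    return out


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tk\tn\tK\tN\tp\tq\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}\n")
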