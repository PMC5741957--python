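"""Core genomic data types, validation and GFF3/BED readers and writers.

Coordinates are 1-based, fully closed (GFF3 convention) everywhere inside the
package.  BED input (0-based, half-open) is converted at the reader boundary.
Strand ``"."`` denotes unstranded evidence and is treated as compatible with
either strand in every strand-match test, because EST-derived alignments are
frequently unstranded.
"""

from __future__ import annotations

import io
import logging
import urllib.parse
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

log = logging.getLogger("droughtgenes")

STRANDS = ("+", "-", ".")

ANNOTATION_STATUSES = (
    "characterised",
    "hypothetical",
    "putatively_uncharacterised",
    "unknown",
)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Report-style percentage, rounded half-away-from-zero to `decimals`.

    All headline fractions in the reports (drought-responsive share,
    co-localization rate, annotation-update rate ...) go through this single
    helper so rounding is consistent across modules.
    """
    if denominator == 0:
        return 0.0
    x = 100.0 * numerator / denominator
    shift = 10**decimals
    import math

    return math.floor(abs(x) * shift + 0.5) / shift * (1 if x >= 0 else -1)


def round1(x: float, decimals: int = 1) -> float:
    """Half-away-from-zero rounding used in tabular reports."""
    import math

    shift = 10**decimals
    return math.floor(abs(x) * shift + 0.5) / shift * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Interval and gene-structure types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed interval on a reference sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base (seq_id aware)."""
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start) + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


def strands_compatible(a: str, b: str) -> bool:
    """Unstranded ('.') evidence matches either strand."""
    return a == "." or b == "." or a == b


@dataclass(frozen=True)
class Transcript:
    """An exon chain with optional UTR intervals and codon flags."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()
    has_start_codon: bool = False
    has_stop_codon: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "utr5", tuple(self.utr5))
        object.__setattr__(self, "utr3", tuple(self.utr3))

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons (empty for single-exon transcripts)."""
        ex = sorted(self.exons, key=lambda e: e.start)
        out = []
        for left, right in zip(ex, ex[1:]):
            if right.start - left.end >= 2:
                out.append(
                    GenomicInterval(self.seq_id, left.end + 1, right.start - 1, self.strand)
                )
        return tuple(out)

    def validate(self) -> list[str]:
        """Violation messages; empty iff the transcript invariants hold."""
        v: list[str] = []
        seq_ids = {e.seq_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seq_ids) > 1:
            v.append(f"transcript {self.transcript_id}: exons on multiple seq_ids {seq_ids}")
        if len(strands) > 1:
            v.append(f"transcript {self.transcript_id}: exons on multiple strands {strands}")
        ex = list(self.exons)
        if ex != sorted(ex, key=lambda e: e.start):
            v.append(f"transcript {self.transcript_id}: exons not sorted by start")
        ex_sorted = sorted(ex, key=lambda e: e.start)
        for left, right in zip(ex_sorted, ex_sorted[1:]):
            if right.start <= left.end:
                v.append(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{left.start},{left.end}] and [{right.start},{right.end}]"
                )
        if not v:
            span = self.span
            for name, utrs in (("utr5", self.utr5), ("utr3", self.utr3)):
                for u in utrs:
                    if not span.contains(u):
                        v.append(
                            f"transcript {self.transcript_id}: {name} interval "
                            f"[{u.start},{u.end}] outside transcript span"
                        )
        return v


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts; span covers all transcript exons."""

    gene_id: str
    span: GenomicInterval
    transcripts: tuple[Transcript, ...]
    annotation_status: str = "unknown"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if self.annotation_status not in ANNOTATION_STATUSES:
            raise ValueError(
                f"gene {self.gene_id}: annotation_status {self.annotation_status!r} "
                f"not in {ANNOTATION_STATUSES}"
            )

    @classmethod
    def from_transcripts(
        cls,
        gene_id: str,
        transcripts: Sequence[Transcript],
        annotation_status: str = "unknown",
    ) -> "GeneModel":
        """Build a gene whose span is recomputed from the transcript exons."""
        txs = tuple(transcripts)
        if not txs:
            raise ValueError(f"gene {gene_id}: no transcripts")
        seq_id = txs[0].seq_id
        strand = txs[0].strand
        span = GenomicInterval(
            seq_id,
            min(e.start for t in txs for e in t.exons),
            max(e.end for t in txs for e in t.exons),
            strand,
        )
        return cls(gene_id, span, txs, annotation_status)

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        seq_id: str,
        exons: Sequence[tuple[int, int]],
        strand: str = "+",
        annotation_status: str = "unknown",
        **tx_kwargs,
    ) -> "GeneModel":
        """Convenience constructor for a single-transcript gene."""
        tx = Transcript(
            f"{gene_id}.1",
            tuple(GenomicInterval(seq_id, s, e, strand) for s, e in exons),
            **tx_kwargs,
        )
        return cls.from_transcripts(gene_id, (tx,), annotation_status)

    @property
    def seq_id(self) -> str:
        return self.span.seq_id

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def representative(self) -> Transcript:
        return self.transcripts[0]

    @property
    def all_exons(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            sorted((e for t in self.transcripts for e in t.exons), key=lambda e: e.start)
        )


def validate_model(model: GeneModel) -> list[str]:
    """Collect invariant violations; the validator never raises.

    Returns an empty list iff the model is well formed: transcripts share one
    seq_id/strand, exons are sorted and disjoint, UTRs lie within spans and the
    gene span equals the envelope of all transcript exons.
    """
    v: list[str] = []
    for t in model.transcripts:
        v.extend(t.validate())
    seq_ids = {t.seq_id for t in model.transcripts}
    strands = {t.strand for t in model.transcripts}
    if len(seq_ids) > 1:
        v.append(f"gene {model.gene_id}: transcripts on multiple seq_ids {seq_ids}")
    if len(strands) > 1:
        v.append(f"gene {model.gene_id}: transcripts on multiple strands {strands}")
    if seq_ids and model.span.seq_id not in seq_ids:
        v.append(f"gene {model.gene_id}: span seq_id differs from transcript seq_id")
    lo = min(e.start for t in model.transcripts for e in t.exons)
    hi = max(e.end for t in model.transcripts for e in t.exons)
    if (model.span.start, model.span.end) != (lo, hi):
        v.append(
            f"gene {model.gene_id}: span [{model.span.start},{model.span.end}] does not "
            f"equal exon envelope [{lo},{hi}]"
        )
    return v


# ---------------------------------------------------------------------------
# Pipeline thresholds
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline in one place.

    Inclusive/exclusive semantics follow the wording each threshold was stated
    with: mapping identity ("at least 80%") and assembly validity ("95% / 90%")
    are inclusive (>=); novel-gene length ("greater than 200 bps"), evidence
    support ("more than 50"), ortholog identity ("more than 50%") and QTL hit
    identity (">80") are exclusive (>).
    """

    min_identity_map: float = 80.0       # % — HSP retention before chaining
    evalue_map: float = 1e-10            # HSP e-value ceiling
    max_chain_span: int = 2000           # bp — maximum genomic span of an HSP chain
    pasa_min_identity: float = 95.0      # % — assembled alignment validity
    pasa_min_coverage: float = 90.0      # % — assembled alignment validity
    min_gene_length: int = 200           # bp, exclusive — novel-gene criterion 2
    min_score: float = 0.5               # [0,1], inclusive — novel-gene criterion 3
    min_evidence_support: float = 50.0   # %, exclusive — novel-gene criterion 4
    min_intergenic_distance: int = 100   # bp — novel-gene criterion 5
    fold_change_min: float = 2.0         # ratio for up/down calls
    p_ttest: float = 0.01
    p_rp: float = 0.01
    p_fisher: float = 0.05
    fdr_alpha: float = 0.05
    ortholog_min_identity: float = 50.0  # %, exclusive
    qtl_hit_max_evalue: float = 1e-10    # exclusive ceiling for QTL alignment hits
    qtl_hit_min_identity: float = 80.0   # %, exclusive
    rp_permutations: int = 10000
    rng_seed: int = 0
    # secondary knobs
    compare_min_overlap: float = 80.0    # % reciprocal span overlap before applying updates
    max_utr_exons: int = 2               # UTR exons added per gene end
    mixed_clusters_confer_drought: bool = True
    strict_filter: bool = False          # require all five novel-gene criteria
    pseudocount_counts: float = 1.0
    pseudocount_abundance: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "min_identity_map",
            "pasa_min_identity",
            "pasa_min_coverage",
            "min_evidence_support",
            "ortholog_min_identity",
            "qtl_hit_min_identity",
            "compare_min_overlap",
        ):
            val = getattr(self, name)
            if not (0 <= val <= 100):
                raise ValueError(f"{name} must be in [0,100], got {val}")
        if not (0 <= self.min_score <= 1):
            raise ValueError(f"min_score must be in [0,1], got {self.min_score}")
        if self.rp_permutations < 100:
            raise ValueError("rp_permutations must be >= 100")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


QGW_FINE_MAPPING_PRESET = {"qtl_hit_max_evalue": 1e-100}
"""QTL-hit screening profile for fine-mapped regions (stringent e-value)."""


# ---------------------------------------------------------------------------
# GFF3 reader / writer
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _esc(value: str) -> str:
    return urllib.parse.quote(value, safe=" :^*$@!+?|[]{}/()'~<>.-_")


def _unesc(value: str) -> str:
    return urllib.parse.unquote(value)


def _prefilter_gff(path: Path, strict: bool) -> str:
    """Screen raw GFF3 rows before handing them to the parser.

    Lenient mode drops malformed rows (bad column count, non-integer or
    inverted coordinates) with a warning; strict mode aborts on the first one.
    """
    kept: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                kept.append(stripped)
                continue
            cols = stripped.split("\t")
            problem = None
            if len(cols) != _GFF_COLS:
                problem = f"expected {_GFF_COLS} columns, got {len(cols)}"
            else:
                try:
                    start, end = int(cols[3]), int(cols[4])
                except ValueError:
                    problem = "non-integer coordinates"
                else:
                    if start > end or start < 1:
                        problem = f"malformed coordinates {start}>{end}" if start > end else "start < 1"
            if problem is None:
                kept.append(stripped)
            elif strict:
                raise ValueError(f"{path}:{lineno}: {problem}")
            else:
                warnings.warn(f"{path}:{lineno}: {problem}; record skipped")
    return "\n".join(kept) + "\n"


def parse_gene_models(path: str | Path, strict: bool = False) -> list[GeneModel]:
    """Read gene/mRNA/exon/UTR features from a GFF3 file into GeneModels.

    Children are attached through their ``Parent`` attribute; spans are
    recomputed from the exons so a stale span column in the input cannot leak
    through.  Orphan children (Parent never defined) are skipped with a
    warning.  Duplicate gene IDs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = _prefilter_gff(path, strict)
    if not any(line and not line.startswith("#") for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        merge_strategy="error",
        keep_order=True,
    )
    gene_ids_seen: set[str] = set()
    models: list[GeneModel] = []
    known_ids = {f.id for f in db.all_features()}
    for gene in db.features_of_type("gene"):
        if gene.id in gene_ids_seen:
            raise ValueError(f"duplicate gene id {gene.id!r} in {path}")
        gene_ids_seen.add(gene.id)
        status = gene.attributes.get("annotation_status", ["unknown"])[0]
        transcripts: list[Transcript] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons, utr5, utr3 = [], [], []
            for child in db.children(mrna, order_by="start"):
                iv = GenomicInterval(child.seqid, child.start, child.end, child.strand)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            if not exons:
                warnings.warn(f"mRNA {mrna.id} in {path} has no exons; skipped")
                continue
            attrs = mrna.attributes
            transcripts.append(
                Transcript(
                    mrna.id,
                    tuple(sorted(exons, key=lambda e: e.start)),
                    tuple(utr5),
                    tuple(utr3),
                    has_start_codon=attrs.get("has_start_codon", ["false"])[0] == "true",
                    has_stop_codon=attrs.get("has_stop_codon", ["false"])[0] == "true",
                )
            )
        if not transcripts:
            warnings.warn(f"gene {gene.id} in {path} has no usable transcripts; skipped")
            continue
        models.append(GeneModel.from_transcripts(gene.id, tuple(transcripts), status))
    # orphan children: features with a Parent that is not defined anywhere
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                warnings.warn(f"orphan feature {feat.id} (Parent={parent_id}) skipped")
    return models


def _bool_attr(flag: bool) -> str:
    return "true" if flag else "false"


def gene_to_gff3_rows(model: GeneModel) -> list[str]:
    rows = []
    s = model.span
    rows.append(
        "\t".join(
            [
                s.seq_id,
                "droughtgenes",
                "gene",
                str(s.start),
                str(s.end),
                ".",
                s.strand,
                ".",
                f"ID={_esc(model.gene_id)};annotation_status={model.annotation_status}",
            ]
        )
    )
    for t in model.transcripts:
        ts = t.span
        rows.append(
            "\t".join(
                [
                    ts.seq_id,
                    "droughtgenes",
                    "mRNA",
                    str(ts.start),
                    str(ts.end),
                    ".",
                    ts.strand,
                    ".",
                    f"ID={_esc(t.transcript_id)};Parent={_esc(model.gene_id)};"
                    f"has_start_codon={_bool_attr(t.has_start_codon)};"
                    f"has_stop_codon={_bool_attr(t.has_stop_codon)}",
                ]
            )
        )
        for ftype, ivs in (
            ("exon", t.exons),
            ("five_prime_UTR", t.utr5),
            ("three_prime_UTR", t.utr3),
        ):
            for i, iv in enumerate(ivs, 1):
                rows.append(
                    "\t".join(
                        [
                            iv.seq_id,
                            "droughtgenes",
                            ftype,
                            str(iv.start),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            f"ID={_esc(t.transcript_id)}.{ftype}.{i};"
                            f"Parent={_esc(t.transcript_id)}",
                        ]
                    )
                )
    return rows


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as GFF3.  Refuses invalid models; output is byte-stable."""
    models = list(models)
    for m in models:
        violations = validate_model(m)
        if violations:
            raise ValueError(f"refusing to write invalid model: {violations}")
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for m in models:
        for row in gene_to_gff3_rows(m):
            buf.write(row + "\n")
    Path(path).write_text(buf.getvalue())
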