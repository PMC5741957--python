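"""End-to-end orchestration: stage order, reports, manifest.

Stage order: alignment validation -> overlap classification -> annotation
update -> novel-gene filtering -> expression statistics -> enrichment and
ortholog screening -> QTL co-localization.  A run ends with a non-redundant
candidate-gene table pooling drought-labelled known genes, passing novel
genes, consensus DE genes and orthology-supported genes, with per-source
provenance flags and QTL co-localization columns.  All randomness flows from
one top-level seed; reports are byte-stable across identical runs (the
manifest, which records wall-clock timings, is the one exception).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .alignment import GeneIndex, validate_alignment, write_alignment_table
from .enrichment import screen_orthologs, sea_enrichment, write_enrichment
from .expression import de_analysis, write_expression
from .model import PipelineConfig, parse_gene_models, write_gene_models
from .novel import (
    NovelGeneCandidate,
    apply_filter,
    exon_intron_stats,
    summarize_novel_genes,
    write_verdicts,
)
from .overlap import (
    OverlapCategory,
    call_transcript,
    label_genes_drought,
    write_overlap_calls,
)
from .qtl import colocalize, summarize_associations, write_associations, write_qtl_bed
from .synthetic import (
    gen_alignments,
    gen_annotation,
    gen_aux,
    gen_expression,
    gen_orthologs,
    gen_update_evidence,
)
from .update import summarize_updates, two_round_compare, write_update_records

DEFAULT_CATEGORY_HISTOGRAM = {c: 8 for c in OverlapCategory}


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "input_checksums": self.input_checksums,
                "stage_timings": self.stage_timings,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path | None = None,
) -> RunManifest:
    """Execute the full pipeline from a config mapping or YAML path.

    With ``synthetic: true`` every input is generated from the top-level seed;
    otherwise the config must name the input files.  Returns the manifest,
    which is also written to ``<outdir>/manifest.json``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = PipelineConfig.from_dict(config.get("thresholds", {}))
    seed = int(config.get("seed", 0))
    out = Path(outdir or config.get("outdir", "run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config), version=__version__)
    timings = manifest.stage_timings

    def _stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 4)

        return _T()

    synthetic = bool(config.get("synthetic", False))
    synth_params = dict(config.get("synthetic_params", {}))

    with _stage("inputs"):
        if synthetic:
            n_genes = int(synth_params.get("n_genes", 60))
            n_seqids = int(synth_params.get("n_seqids", 3))
            genes, _ = gen_annotation(n_genes, n_seqids, seed=seed)
            hist = {
                OverlapCategory(k): v
                for k, v in synth_params.get(
                    "category_histogram",
                    {c.value: 8 for c in OverlapCategory},
                ).items()
            }
            alignments, overlap_truth = gen_alignments(genes, hist, seed=seed + 1)
            update_evidence, update_truth = gen_update_evidence(
                genes, seed=seed + 2
            )
            libraries, clusters, term_map, qtls, aux_truth = gen_aux(
                genes, overlap_truth, seed=seed + 3
            )
            matrix, de_truth = gen_expression(
                n_genes=int(synth_params.get("n_expr_genes", 400)),
                de_fraction=float(synth_params.get("de_fraction", 0.02)),
                log2fc=float(synth_params.get("log2fc", 2.0)),
                sigma=float(synth_params.get("sigma", 0.25)),
                seed=seed + 4,
            )
            orthologs = gen_orthologs([g.gene_id for g in genes], seed=seed + 5)
            novel_candidates = _synthetic_novel_candidates(genes, aux_truth, seed + 6)
        else:
            inputs = config.get("inputs", {})
            required = ("annotation",)
            missing = [k for k in required if k not in inputs]
            if missing:
                raise FileNotFoundError(f"missing required inputs: {missing}")
            genes = parse_gene_models(inputs["annotation"])
            for key, p in inputs.items():
                manifest.input_checksums[key] = _sha256(Path(p))
            raise NotImplementedError(
                "file-based runs require all stage inputs; use synthetic: true "
                "for a self-contained run"
            )

    with _stage("alignment_filter"):
        validated = [validate_alignment(a, cfg) for a in alignments]
        valid = [a for a in validated if a.valid]
        write_alignment_table(validated, out / "alignments.tsv")

    with _stage("overlap_classifier"):
        index = GeneIndex(genes)
        calls = [call_transcript(a, index) for a in valid]
        write_overlap_calls(calls, out / "overlap_calls.tsv")
        drought_labels = label_genes_drought(calls, clusters, cfg)
        with open(out / "drought_labels.tsv", "w") as fh:
            fh.write("gene_id\tdrought_responsive\n")
            for gid, flag in sorted(drought_labels.items()):
                fh.write(f"{gid}\t{int(flag)}\n")

    with _stage("annotation_update"):
        evidence_calls = [
            (aln, call_transcript(aln, index)) for aln, _gene in update_evidence
        ]
        updated_genes, records, second_round = two_round_compare(
            genes, evidence_calls, cfg
        )
        write_update_records(records, out / "update_records.tsv")
        summary = summarize_updates(records, total_genes=len(genes))
        summary["second_round_records"] = len(second_round)
        (out / "update_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        write_gene_models(updated_genes, out / "updated_annotation.gff3")

    with _stage("novel_gene_filter"):
        verdicts = [apply_filter(c, genes, cfg) for c in novel_candidates]
        write_verdicts(verdicts, out / "novel_verdicts.tsv")
        passing = [
            c
            for c, v in zip(novel_candidates, verdicts)
            if v.passed
        ]
        stats = exon_intron_stats([c.model for c in passing]) if passing else pd.DataFrame()
        stats.to_csv(out / "exon_intron_stats.tsv", sep="\t", index=False)
        novel_summary = summarize_novel_genes(passing)
        (out / "novel_summary.json").write_text(
            json.dumps(novel_summary, indent=2, sort_keys=True) + "\n"
        )

    with _stage("expression_stats"):
        grouping = config.get("grouping", "treatment")
        tests = tuple(config.get("tests", ("ttest", "rp", "fisher")))
        de_table, cons = de_analysis(matrix, grouping, cfg, tests=tests)
        de_table.to_csv(out / "de_results.tsv", sep="\t", float_format="%.6g")
        write_expression(matrix, out / "expression.tsv", out / "samples.tsv")

    with _stage("enrichment_orthology"):
        study = sorted(gid for gid, flag in drought_labels.items() if flag)
        enr = sea_enrichment(study, term_map, cfg) if study else []
        write_enrichment(enr, out / "enrichment.tsv")
        retained = screen_orthologs(orthologs, cfg)
        with open(out / "orthologs_retained.tsv", "w") as fh:
            fh.write("source_gene\ttarget_gene\tspecies\tidentity\tconfidence\ttype\n")
            for r in retained:
                fh.write(
                    f"{r.source_gene}\t{r.target_gene}\t{r.species}\t"
                    f"{r.percent_identity:g}\t{r.confidence}\t{r.homology_type}\n"
                )

    with _stage("qtl_colocalization"):
        candidate_sources: dict[str, set[str]] = {
            "drought_overlap": {g for g, f in drought_labels.items() if f},
            "novel": {
                c.model.gene_id for c in passing if c.drought_responsive
            },
            "de_consensus": set(cons["intersection"]),
            "orthology": {r.source_gene for r in retained}
            & {g for g, f in drought_labels.items() if f},
        }
        union = sorted(set().union(*candidate_sources.values()))
        gene_by_id = {g.gene_id: g for g in genes}
        for c in passing:
            gene_by_id.setdefault(c.model.gene_id, c.model)
        coloc_genes = [gene_by_id[g] for g in union if g in gene_by_id]
        assocs = colocalize(coloc_genes, qtls)
        write_associations(assocs, out / "qtl_associations.tsv")
        write_qtl_bed(qtls, out / "qtls.bed")
        qtl_summary = summarize_associations(assocs, total_input_genes=len(union))
        (out / "qtl_summary.json").write_text(
            json.dumps(qtl_summary, indent=2, sort_keys=True) + "\n"
        )
        qtl_by_gene: dict[str, list[str]] = {}
        for a in assocs:
            for gid in a.gene_ids:
                qtl_by_gene.setdefault(gid, []).append(a.qtl_id)
        with open(out / "candidate_genes.tsv", "w") as fh:
            fh.write(
                "gene_id\tin_drought_overlap\tin_novel\tin_de_consensus\t"
                "in_orthology\tqtl_ids\n"
            )
            for gid in union:
                flags = "\t".join(
                    str(int(gid in candidate_sources[k]))
                    for k in ("drought_overlap", "novel", "de_consensus", "orthology")
                )
                fh.write(f"{gid}\t{flags}\t{','.join(sorted(qtl_by_gene.get(gid, [])))}\n")

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.outputs[p.name] = _sha256(p)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _synthetic_novel_candidates(genes, aux_truth, seed: int) -> list[NovelGeneCandidate]:
    """Predicted intergenic gene models planted in the annotation's gaps."""
    import numpy as np

    from .model import GeneModel, GenomicInterval
    from .synthetic import MIN_FEATURE, _neighbour_room

    rng = np.random.default_rng(seed)
    room = _neighbour_room(sorted(genes, key=lambda g: (g.seq_id, g.span.start)))
    out: list[NovelGeneCandidate] = []
    n = 0
    for g in sorted(genes, key=lambda g: (g.seq_id, g.span.start)):
        left, _right = room[g.gene_id]
        if left < 2 * MIN_FEATURE + 2 * 100 + 10:
            continue
        n += 1
        length = int(rng.integers(201, max(202, left - 2 * 100)))
        start = g.span.start - 100 - length
        if start < 1:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 3))
        if n_ex == 2 and length >= 3 * MIN_FEATURE:
            third = length // 3
            exons = [
                (start, start + third - 1),
                (start + 2 * third, start + length - 1),
            ]
        else:
            exons = [(start, start + length - 1)]
        model = GeneModel.from_exons(
            f"NG{n:04d}", g.seq_id, exons, strand,
            has_start_codon=True, has_stop_codon=True,
        )
        evidence_type = "homology" if rng.random() < 0.55 else "ab_initio"
        out.append(
            NovelGeneCandidate(
                model,
                score=round(float(rng.uniform(0.3, 1.0)), 2),
                evidence_type=evidence_type,
                evidence_support=round(float(rng.uniform(40, 100)), 1)
                if evidence_type == "homology"
                else None,
                drought_responsive=bool(rng.random() < 0.6),
            )
        )
        if n >= 30:
            break
    return out
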