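"""End-to-end orchestration: CTSS filter -> clusters -> promoters -> annotation ->
differential/alt-usage -> shifts -> allelic imbalance, with a summary and manifest."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import CtssMatrix, SampleSheet
from . import io as cio
from .ctss import filter_ctss
from .clustering import (cluster_ctss, normalize_tpm, filter_clusters,
                         group_promoters, clusters_to_frame, promoters_to_frame)
from .annotation import assign_and_rank, classify_arch
from .altpromoter import test_differential, call_alt_usage_all
from .shift import call_shifts
from .ase import (filter_variants_for_ase, test_allelic_imbalance,
                  classify_variant_promoters, compare_promoter_classes)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline, with the published defaults."""

    ctss_min_samples: int = 3
    ctss_min_count: int = 1
    tc_gap: int = 20
    promoter_gap: int = 100
    min_tpm: float = 1.0
    upstream_bp: int = 1000
    cpg_flank: int = 200
    tata_window: tuple[int, int] = (-500, 200)
    min_prop: float = 0.2
    de_alpha: float = 0.05
    shift_d_min: float = 0.3
    shift_alpha: float = 0.05
    ase_min_reads: int = 10
    ase_f1_min_replicates: int = 9
    ase_alpha: float = 0.05
    de_lfc_min_for_class: float = 1.0
    strain_a: str = "A"
    strain_b: str = "B"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.tata_window = tuple(cfg.tata_window)
        return cfg


@dataclass
class PipelineResult:
    clusters: list
    promoters: list
    annotations: list
    de: pd.DataFrame
    alt_calls: dict
    shift_calls: list
    ase_results: list = field(default_factory=list)
    ase_report: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, matrix: CtssMatrix, samplesheet: SampleSheet,
                 genes=None, cpg_islands: pd.DataFrame | None = None,
                 genome: dict[str, str] | None = None,
                 variants=None, outdir=None) -> PipelineResult:
    """Run all stages on an in-memory CTSS matrix; optionally write stage outputs."""
    t0 = time.time()
    parental = [s for s in samplesheet.samples
                if samplesheet.frame.set_index("sample_id")["strain"][s]
                in (config.strain_a, config.strain_b)]
    pmatrix = matrix.subset_samples(parental) if parental else matrix

    def stage(name):
        log.info("[%7.2fs] stage: %s", time.time() - t0, name)

    stage("ctss filter")
    filtered = filter_ctss(pmatrix, config.ctss_min_samples, config.ctss_min_count)

    stage("clustering")
    clusters = cluster_ctss(filtered, config.tc_gap)
    if clusters:
        clusters = normalize_tpm(clusters, filtered.sample_totals)
        clusters = filter_clusters(clusters, config.min_tpm)
    promoters = group_promoters(clusters, config.promoter_gap)

    stage("annotation")
    annotations = []
    if genes is not None:
        annotations = assign_and_rank(promoters, genes, config.upstream_bp)
        if cpg_islands is not None and genome is not None:
            for ann, p in zip(annotations, promoters):
                ann.arch_class = classify_arch(p, cpg_islands, genome,
                                               config.cpg_flank, config.tata_window)
    else:
        for p in promoters:
            p.rank = 1

    stage("differential expression")
    counts = pd.DataFrame({p.promoter_id: p.counts for p in promoters}).T
    de = pd.DataFrame(columns=["mean_expression", "log2fc", "se", "p", "padj"])
    alt_calls = {}
    if len(counts):
        counts.columns = promoters[0].samples
        de = test_differential(counts, samplesheet, config.strain_a, config.strain_b)
        if genes is not None:
            alt_calls = call_alt_usage_all(promoters, de, config.min_prop,
                                           config.de_alpha)

    stage("shift detection")
    samples_a = samplesheet.strain_samples(config.strain_a)
    samples_b = samplesheet.strain_samples(config.strain_b)
    tc_rank = {}
    for p in promoters:
        for tc in p.clusters:
            tc_rank[tc.tc_id] = (p.gene_id, p.rank)
    shift_calls = []
    if samples_a and samples_b and clusters:
        shift_calls = call_shifts(filtered, clusters, samples_a, samples_b,
                                  config.shift_d_min, config.shift_alpha, tc_rank)

    stage("allelic imbalance")
    ase_results, ase_report = [], {}
    if variants is not None:
        usable = filter_variants_for_ase(
            variants, samplesheet, config.strain_a, config.strain_b, "F1",
            config.ase_min_reads, config.ase_f1_min_replicates)
        ase_results = test_allelic_imbalance(usable, samplesheet, "F1", config.ase_alpha)
        ase_results = classify_variant_promoters(
            ase_results, promoters, shift_calls, de,
            config.de_alpha, config.de_lfc_min_for_class)
        ase_report = compare_promoter_classes(ase_results)

    summary = _summarize(clusters, promoters, annotations, alt_calls,
                         shift_calls, ase_results, ase_report)
    result = PipelineResult(clusters=clusters, promoters=promoters,
                            annotations=annotations, de=de, alt_calls=alt_calls,
                            shift_calls=shift_calls, ase_results=ase_results,
                            ase_report=ase_report, summary=summary)
    if outdir is not None:
        _write_outputs(result, config, Path(outdir))
    stage("done")
    return result


def _summarize(clusters, promoters, annotations, alt_calls, shift_calls,
               ase_results, ase_report) -> dict:
    genic = [p for p in promoters if p.gene_id is not None]
    per_gene: dict[str, int] = {}
    for p in genic:
        per_gene[p.gene_id] = per_gene.get(p.gene_id, 0) + 1
    hist: dict[int, int] = {}
    for n in per_gene.values():
        hist[n] = hist.get(n, 0) + 1
    arch_counts: dict[str, int] = {}
    for a in annotations:
        if a.arch_class is not None:
            arch_counts[a.arch_class] = arch_counts.get(a.arch_class, 0) + 1
    tss_counts: dict[str, int] = {}
    for a in annotations:
        tss_counts[a.tss_class] = tss_counts.get(a.tss_class, 0) + 1
    cat_counts: dict[str, int] = {}
    for call in alt_calls.values():
        cat_counts[call.category] = cat_counts.get(call.category, 0) + 1
    sig_shifts = [c for c in shift_calls if c.significant]
    p1_share = (sum(1 for c in sig_shifts if c.rank == 1) / len(sig_shifts)
                if sig_shifts else None)
    return {
        "n_tag_clusters": len(clusters),
        "n_promoter_regions": len(promoters),
        "n_genic_promoters": len(genic),
        "n_intergenic_promoters": len(promoters) - len(genic),
        "promoters_per_gene_hist": hist,
        "tss_class_counts": tss_counts,
        "arch_class_counts": arch_counts,
        "alt_usage_categories": cat_counts,
        "n_shift_calls": len(shift_calls),
        "n_significant_shifts": len(sig_shifts),
        "p1_share_of_significant_shifts": p1_share,
        "n_ase_variants_tested": len(ase_results),
        "ase_class_report": {k: v for k, v in ase_report.items() if k != "fisher_table"},
    }


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    clusters_to_frame(result.clusters).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    promoters_to_frame(result.promoters).to_csv(outdir / "promoters.tsv", sep="\t", index=False)
    if result.annotations:
        pd.DataFrame([{
            "promoter_id": a.promoter_id, "gene_id": a.gene_id or "",
            "rank": a.rank if a.rank is not None else "",
            "tss_class": a.tss_class, "arch_class": a.arch_class or "",
        } for a in result.annotations]).to_csv(outdir / "promoters.annotated.tsv",
                                               sep="\t", index=False)
    result.de.rename_axis("promoter_id").to_csv(outdir / "de.tsv", sep="\t")
    if result.alt_calls:
        pd.DataFrame([{
            "gene_id": c.gene_id, "category": c.category,
            "active_promoters": ",".join(c.active_promoters),
            "evidence": ",".join(c.evidence) if c.evidence else "",
        } for c in result.alt_calls.values()]).to_csv(outdir / "alt_usage.tsv",
                                                      sep="\t", index=False)
    if result.shift_calls:
        pd.DataFrame([{
            "cluster_id": c.cluster_id, "D": c.D, "critical_value": c.critical_value,
            "shift_pos": c.shift_pos, "direction": c.direction,
            "significant": c.significant, "n_a": c.n_a, "n_b": c.n_b,
            "shift_distance": c.shift_distance, "gene_id": c.gene_id or "",
            "rank": c.rank if c.rank is not None else "",
        } for c in result.shift_calls]).to_csv(outdir / "shifts.tsv", sep="\t", index=False)
    if result.ase_results:
        pd.DataFrame([{
            "chrom": r.variant.chrom, "pos": r.variant.pos,
            "ref": r.variant.ref, "alt": r.variant.alt,
            "ref_total": r.ref_total, "alt_total": r.alt_total, "AI": r.AI,
            "p_binomial": r.p_binomial, "significant": r.significant,
            "promoter_id": r.promoter_id or "", "promoter_class": r.promoter_class or "",
        } for r in result.ase_results]).to_csv(outdir / "ase.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=str)
    cfg_dict = asdict(config)
    manifest = {
        "version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in cfg_dict.items()},
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def run_from_files(config: PipelineConfig, ctss_path, samplesheet_path,
                   gtf_path=None, cpg_path=None, fasta_path=None,
                   vcf_path=None, outdir=None) -> PipelineResult:
    """File-based entry point used by the CLI; any stage failure names the stage."""
    matrix = cio.read_ctss_table(ctss_path)
    sheet = SampleSheet.from_tsv(samplesheet_path)
    genes = cio.read_gene_models(gtf_path) if gtf_path else None
    cpg = cio.read_bed_intervals(cpg_path) if cpg_path else None
    genome = cio.read_fasta(fasta_path) if fasta_path else None
    variants = cio.read_variants(vcf_path) if vcf_path else None
    return run_pipeline(config, matrix, sheet, genes, cpg, genome, variants, outdir)
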