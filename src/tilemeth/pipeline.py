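"""End-to-end orchestration: tiling -> cDMR/cLMR calling -> annotation ->
expression integration -> motif and GWAS-SNP enrichment, from one config."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .annotate import annotate_regions, feature_enrichment, enrichment_table, region_gene_map
from .dmr import call_cdmrs, classify_clmrs, summarize_clmr_uniqueness
from .integrate import (
    background_correlation_test,
    clmr_gene_set_enrichment,
    correlate_methylation_expression,
    gwas_snp_enrichment,
    sign_enrichment_test,
)
from .io import (
    SampleMeta,
    read_cgi_bed,
    read_cpg_report,
    read_enriched_genes,
    read_fasta,
    read_gene_bed12,
    read_meme_pwms,
    read_snp_table,
    read_tpm_table,
    write_region_tables,
)
from .motifs import enrichment_matrix, motif_enrichment_test
from .tiling import FilterSpec, apply_coverage_filter, tile_counts


@dataclass
class PipelineConfig:
    """All paths and thresholds for one run. Defaults are the study values:
    1 kb tiles, coverage > 25 in >= 7 cell types per animal, FDR < 0.01,
    z < -1 and mean methylation < 75% for cLMRs, 2 kb promoters."""

    cpg_reports: dict[str, str] = field(default_factory=dict)  # sample_id -> path
    sample_sheet: list[dict[str, str]] = field(default_factory=list)
    genes_bed: str | None = None
    cgi_bed: str | None = None
    tpm_table: str | None = None
    enriched_genes: str | None = None
    snp_table: str | None = None
    motifs_meme: str | None = None
    positive_fasta: str | None = None
    control_fasta: str | None = None
    outdir: str = "tilemeth_out"

    tile_size: int = 1000
    min_coverage: int = 25
    min_cell_types: int = 7
    per_animal: bool = True
    fdr_threshold: float = 0.01
    z_cut: float = -1.0
    meth_cut: float = 0.75
    promoter_bp: int = 2000
    tts_bp: int = 1000
    shore_bp: int = 2000
    alpha: float = 0.05
    log_tpm: bool = True
    motif_zero_floor: float = 1e-4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(r["sample_id"], r["cell_type"], r["animal"])
            for r in self.sample_sheet
        ]


def validate_config(config: PipelineConfig) -> list[str]:
    """List every violation; never mutates state; empty list = valid."""
    v: list[str] = []
    if config.tile_size <= 0:
        v.append("tile_size must be positive")
    if config.min_coverage < 0:
        v.append("min_coverage must be non-negative")
    if not 0.0 < config.fdr_threshold <= 1.0:
        v.append("fdr_threshold must be in (0, 1]")
    if not 0.0 <= config.meth_cut <= 1.0:
        v.append("meth_cut must be in [0, 1]")
    if not 0.0 < config.alpha < 1.0:
        v.append("alpha must be in (0, 1)")
    if config.promoter_bp < 0 or config.tts_bp < 0 or config.shore_bp < 0:
        v.append("window sizes must be non-negative")
    samples = config.samples()
    cell_types = {s.cell_type for s in samples}
    if samples and config.min_cell_types > len(cell_types):
        v.append(
            f"min_cell_types={config.min_cell_types} exceeds the "
            f"{len(cell_types)} cell types in the sample sheet"
        )
    pairs = [(s.cell_type, s.animal) for s in samples]
    if len(set(pairs)) != len(pairs):
        v.append("duplicate (cell_type, animal) pairs in sample sheet")
    for sid in config.cpg_reports:
        if sid not in {s.sample_id for s in samples}:
            v.append(f"report for unknown sample {sid!r}")
    for name in (
        "genes_bed", "cgi_bed", "tpm_table", "enriched_genes",
        "snp_table", "motifs_meme", "positive_fasta", "control_fasta",
    ):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            v.append(f"{name} path does not exist: {path}")
    for sid, path in config.cpg_reports.items():
        if not Path(path).exists():
            v.append(f"cpg report missing for {sid}: {path}")
    if config.tpm_table is not None and config.genes_bed is None:
        v.append("integration requires genes_bed")
    return v


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage the config has inputs for; returns the manifest.

    Always: tiling, coverage filtering, cDMR calling, cLMR classification
    and the per-cell summary. With gene/CGI inputs: annotation and feature
    enrichment. With a TPM table: correlation, background comparison, sign
    enrichment and (with an enriched-gene table) gene-set enrichment. With a
    SNP table: GWAS enrichment. With FASTA + MEME inputs: motif enrichment.
    Identical config and inputs give identical outputs (backgrounds are
    seeded from ``config.seed``).
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tilemeth_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("cpg_reports", "sample_sheet")
        },
        "stages": {},
    }
    samples = config.samples()

    # -- tiling + filter
    reports = {
        sid: read_cpg_report(path) for sid, path in config.cpg_reports.items()
    }
    tiles = tile_counts(reports, samples, tile_size=config.tile_size)
    spec = FilterSpec(config.min_coverage, config.min_cell_types, config.per_animal)
    retained = apply_coverage_filter(tiles, spec)
    manifest["stages"]["tiling"] = {
        "n_tiles": int(len(tiles.regions)),
        "n_retained": int(len(retained.regions)),
    }

    # -- cDMR + cLMR
    results = call_cdmrs(retained, fdr_threshold=config.fdr_threshold)
    calls = classify_clmrs(results, retained, z_cut=config.z_cut, meth_cut=config.meth_cut)
    n_tested = sum(r.testable for r in results)
    cdmrs = [r for r in results if r.is_cdmr]
    manifest["stages"]["dmr"] = {
        "n_tested": int(n_tested),
        "n_cdmrs": int(len(cdmrs)),
        "n_clmrs": int(sum(c.is_clmr for c in calls)),
        "n_clmr_regions": int(len({c.region_id for c in calls if c.is_clmr})),
    }
    write_region_tables(results, retained, calls, outdir / "regions")

    annotations = None
    gene_map: dict[str, tuple[str, ...]] = {}
    if config.genes_bed is not None:
        genes = read_gene_bed12(config.genes_bed)
        cgis = read_cgi_bed(config.cgi_bed) if config.cgi_bed else []
        region_tuples = [
            (rid, row.chrom, int(row.start), int(row.end))
            for rid, row in retained.regions.iterrows()
        ]
        annotations = annotate_regions(
            region_tuples, genes, cgis,
            promoter_bp=config.promoter_bp, tts_bp=config.tts_bp,
            shore_bp=config.shore_bp,
        )
        gene_map = region_gene_map(annotations)
        clmr_by_cell = {
            cell: {c.region_id for c in calls if c.is_clmr and c.cell_type == cell}
            for cell in retained.cell_types
        }
        enr = feature_enrichment(
            clmr_by_cell, list(retained.regions.index), annotations
        )
        enrichment_table(enr).to_csv(outdir / "feature_enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["annotation"] = {
            "n_genes": len(genes),
            "n_cgis": len(cgis),
        }

    summary = summarize_clmr_uniqueness(calls, gene_map)
    summary.to_csv(outdir / "clmr_summary.tsv", sep="\t")
    manifest["stages"]["clmr_summary"] = {
        "per_cell_totals": {str(k): int(v) for k, v in summary["n_clmrs"].items()}
    }

    if config.tpm_table is not None and annotations is not None:
        tpm = read_tpm_table(config.tpm_table)
        cell_of_sample = {s.sample_id: s.cell_type for s in samples}
        # expression columns may be cell names directly
        for col in tpm.columns:
            cell_of_sample.setdefault(col, col if col in retained.cell_types else None)
        cell_of_sample = {k: v for k, v in cell_of_sample.items() if v}
        corrs = correlate_methylation_expression(
            cdmrs, annotations, retained, tpm, cell_of_sample, config.log_tpm
        )
        comparisons = background_correlation_test(
            corrs, [r.region_id for r in cdmrs], annotations, retained, tpm,
            cell_of_sample, seed=config.seed, log_transform=config.log_tpm,
        )
        bg_corr_ids = [rid for comp in comparisons.values() for rid in comp.background_regions]
        from .integrate import correlate_regions

        bg_corrs = correlate_regions(
            bg_corr_ids, annotations, retained, tpm, cell_of_sample, config.log_tpm
        )
        signs = sign_enrichment_test(corrs, bg_corrs, alpha=config.alpha)
        manifest["stages"]["integration"] = {
            "n_correlations": len(corrs),
            "wilcoxon_p": {s: comp.rank_sum.p for s, comp in comparisons.items()},
            "sign_enrichment_p": {
                f"{s.stratum}:{s.sign}": s.p for s in signs
            },
        }
        if config.enriched_genes is not None:
            enriched = read_enriched_genes(config.enriched_genes)
            clmr_genes = {
                cell: {
                    g
                    for c in calls
                    if c.is_clmr and c.cell_type == cell
                    for g in gene_map.get(c.region_id, ())
                }
                for cell in retained.cell_types
            }
            enriched_sets = {
                cell: set(sub["gene"])
                for cell, sub in enriched.groupby("cell_type")
            }
            universe = set(tpm.index)
            clmr_genes = {c: s & universe for c, s in clmr_genes.items()}
            enriched_sets = {c: s & universe for c, s in enriched_sets.items()}
            gse = clmr_gene_set_enrichment(clmr_genes, enriched_sets, universe)
            gse.to_csv(outdir / "gene_set_enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["gene_set"] = {"n_tests": len(gse)}

    if config.snp_table is not None:
        snps = read_snp_table(config.snp_table)
        cdmr_regions = [
            (row.chrom, int(row.start), int(row.end))
            for rid, row in retained.regions.iterrows()
            if rid in {r.region_id for r in cdmrs}
        ]
        gwas = gwas_snp_enrichment(snps, cdmr_regions)
        manifest["stages"]["gwas"] = {
            cls: {"observed": e.observed, "expected": e.expected, "p": e.p}
            for cls, e in gwas.items()
        }

    if config.motifs_meme and config.positive_fasta and config.control_fasta:
        pwms = read_meme_pwms(config.motifs_meme)
        pos = read_fasta(config.positive_fasta)
        ctrl = read_fasta(config.control_fasta)
        enr = motif_enrichment_test(
            pos, ctrl, pwms, cell_type="all", zero_floor=config.motif_zero_floor
        )
        mat = enrichment_matrix(enr)
        mat.to_csv(outdir / "motif_enrichment.tsv", sep="\t")
        best = min(enr, key=lambda e: (e.p, e.motif_id))
        manifest["stages"]["motif"] = {
            "n_motifs": len(pwms),
            "top_motif": best.motif_id,
            "top_p": best.p,
        }

    counts = manifest["stages"]["dmr"]
    assert (
        counts["n_clmr_regions"] <= counts["n_cdmrs"] <= counts["n_tested"]
        <= manifest["stages"]["tiling"]["n_tiles"]
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
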