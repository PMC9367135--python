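"""Methylation-expression integration and overlap enrichment layers.

Per cDMR, Pearson correlation between regional methylation and transcript
abundance of the overlapping gene (nearest-TSS gene for intergenic
regions), computed on per-cell means across the cell populations;
distributions are compared against seeded random draws of non-cDMR tiles
from the same feature stratum (one-sided rank-sum for a left shift), signs
of significant correlations are tested with one-sided Fisher's exact tests,
and the gene-set (cLMR genes x expression-enriched genes) and GWAS-SNP
layers use upper-tail hypergeometric tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import FeatureAnnotation
from .io import SNPRecord
from .stats import (
    EnrichmentResult,
    RankSumResult,
    fisher_greater,
    hypergeom_enrichment,
    rank_sum_test,
)
from .tiling import TileMatrix

STRATA = ("promoter", "intragenic", "tts", "intergenic")

_FEATURE_TO_STRATUM = {
    "promoter": "promoter",
    "exon": "intragenic",
    "intron": "intragenic",
    "tts": "tts",
    "intergenic": "intergenic",
}


@dataclass(frozen=True)
class CorrelationResult:
    region_id: str
    gene_id: str
    stratum: str
    r: float
    p: float  # two-sided; NaN when undefined (n < 3 or constant input)
    n: int


def stratum_of(feature_class: str) -> str:
    return _FEATURE_TO_STRATUM[feature_class]


def _log_tpm(tpm: pd.DataFrame, log_transform: bool) -> pd.DataFrame:
    return np.log2(tpm + 1.0) if log_transform else tpm


def _cell_means(
    tpm: pd.DataFrame, cell_of_sample: Mapping[str, str]
) -> pd.DataFrame:
    cols = [c for c in tpm.columns if c in cell_of_sample]
    if not cols:
        raise ValueError("no expression samples map to a cell type")
    groups = pd.Index([cell_of_sample[c] for c in cols], name="cell_type")
    return tpm[cols].T.groupby(groups).mean().T


def _pair_genes(
    ann: FeatureAnnotation,
) -> list[str]:
    if ann.feature_class == "intergenic":
        return [ann.nearest_gene_id] if ann.nearest_gene_id else []
    if ann.feature_gene_ids:
        return list(ann.feature_gene_ids)
    return list(ann.overlapping_gene_ids)


def correlate_regions(
    region_ids: Sequence[str],
    annotations: Sequence[FeatureAnnotation],
    tiles: TileMatrix,
    tpm: pd.DataFrame,
    cell_of_sample: Mapping[str, str],
    log_transform: bool = True,
) -> list[CorrelationResult]:
    """Pearson r between per-cell mean methylation of each region and
    per-cell mean (log2) TPM of its paired gene(s)."""
    ann_by_region = {a.region_id: a for a in annotations}
    expr = _cell_means(_log_tpm(tpm, log_transform), cell_of_sample)
    cells = tiles.cell_types
    meth = pd.DataFrame(
        tiles.cell_mean_rates(), index=tiles.regions.index, columns=cells
    )
    out: list[CorrelationResult] = []
    for rid in region_ids:
        ann = ann_by_region.get(rid)
        if ann is None:
            continue
        stratum = stratum_of(ann.feature_class)
        for gene in _pair_genes(ann):
            if gene not in expr.index:
                continue
            shared = [c for c in cells if c in expr.columns]
            m = meth.loc[rid, shared].to_numpy(dtype=float)
            e = expr.loc[gene, shared].to_numpy(dtype=float)
            keep = np.isfinite(m) & np.isfinite(e)
            m, e = m[keep], e[keep]
            n = int(keep.sum())
            if n < 3 or np.ptp(m) == 0.0 or np.ptp(e) == 0.0:
                out.append(CorrelationResult(rid, gene, stratum, float("nan"), float("nan"), n))
                continue
            r, p = sps.pearsonr(m, e)
            out.append(CorrelationResult(rid, gene, stratum, float(r), float(p), n))
    return out


def correlate_methylation_expression(
    cdmr_results,
    annotations: Sequence[FeatureAnnotation],
    tiles: TileMatrix,
    tpm: pd.DataFrame,
    cell_of_sample: Mapping[str, str],
    log_transform: bool = True,
) -> list[CorrelationResult]:
    """Correlations for the cDMR set (see :func:`correlate_regions`)."""
    cdmr_ids = [r.region_id for r in cdmr_results if getattr(r, "is_cdmr", True)]
    return correlate_regions(
        cdmr_ids, annotations, tiles, tpm, cell_of_sample, log_transform
    )


@dataclass(frozen=True)
class StratumComparison:
    stratum: str
    n_cdmr: int
    n_background: int
    rank_sum: RankSumResult
    background_regions: tuple[str, ...]


def background_correlation_test(
    cdmr_correlations: Sequence[CorrelationResult],
    cdmr_ids: Iterable[str],
    annotations: Sequence[FeatureAnnotation],
    tiles: TileMatrix,
    tpm: pd.DataFrame,
    cell_of_sample: Mapping[str, str],
    seed: int,
    log_transform: bool = True,
) -> dict[str, StratumComparison]:
    """Compare cDMR correlation distributions against a seeded random draw
    of equally many non-cDMR retained tiles per feature stratum; returns the
    one-sided rank-sum p for the cDMR distribution being left-shifted."""
    rng = np.random.default_rng(seed)
    cdmr_set = set(cdmr_ids)
    strata_of_region = {
        a.region_id: stratum_of(a.feature_class) for a in annotations
    }
    pool: dict[str, list[str]] = {s: [] for s in STRATA}
    for rid in tiles.regions.index:
        if rid in cdmr_set:
            continue
        s = strata_of_region.get(rid)
        if s is not None:
            pool[s].append(rid)

    by_stratum: dict[str, list[float]] = {s: [] for s in STRATA}
    for c in cdmr_correlations:
        if not math.isnan(c.r):
            by_stratum[c.stratum].append(c.r)

    out: dict[str, StratumComparison] = {}
    for stratum in STRATA:
        fg = by_stratum[stratum]
        if not fg:
            continue
        avail = pool[stratum]
        if not avail:
            continue  # no background tiles for this stratum
        k = min(len(fg), len(avail))
        drawn = list(rng.choice(avail, size=k, replace=False))
        bg_corrs = correlate_regions(
            drawn, annotations, tiles, tpm, cell_of_sample, log_transform
        )
        bg = [c.r for c in bg_corrs if not math.isnan(c.r)]
        if not bg:
            continue
        res = rank_sum_test(fg, bg, alternative="less")
        out[stratum] = StratumComparison(stratum, len(fg), len(bg), res, tuple(drawn))
    return out


@dataclass(frozen=True)
class SignEnrichment:
    stratum: str
    sign: str  # "positive" or "negative"
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    degenerate: bool = False


def sign_enrichment_test(
    cdmr_correlations: Sequence[CorrelationResult],
    background_correlations: Sequence[CorrelationResult],
    alpha: float = 0.05,
) -> list[SignEnrichment]:
    """Per-stratum, per-sign one-sided Fisher tests for cDMRs being enriched
    in significantly positive/negative methylation-expression correlations
    relative to the background set."""

    def classify(corrs):
        by = {s: {"positive": 0, "negative": 0, "total": 0} for s in STRATA}
        for c in corrs:
            if math.isnan(c.r) or math.isnan(c.p):
                continue
            d = by[c.stratum]
            d["total"] += 1
            if c.p < alpha:
                d["positive" if c.r > 0 else "negative"] += 1
        return by

    fg, bg = classify(cdmr_correlations), classify(background_correlations)
    out: list[SignEnrichment] = []
    for stratum in STRATA:
        for sign in ("positive", "negative"):
            a = fg[stratum][sign]
            b = fg[stratum]["total"] - a
            c = bg[stratum][sign]
            d = bg[stratum]["total"] - c
            table = ((a, b), (c, d))
            if min(a + b, c + d) == 0 or (a + c) == 0:
                out.append(SignEnrichment(stratum, sign, table, float("nan"), 1.0, True))
                continue
            odds, p = fisher_greater(table)
            out.append(SignEnrichment(stratum, sign, table, odds, p))
    return out


def clmr_gene_set_enrichment(
    clmr_genes: Mapping[str, set[str]],
    enriched_genes: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric overlap of cLMR genes (per methylation cell type)
    against expression-enriched genes (per expression cell type)."""
    for name, sets in (("clmr", clmr_genes), ("enriched", enriched_genes)):
        for cell, genes in sets.items():
            outside = genes - universe
            if outside:
                raise ValueError(
                    f"{name} gene(s) outside universe for {cell}: {sorted(outside)[:3]}"
                )
    rows = []
    for cell_a, drawn in sorted(clmr_genes.items()):
        for cell_b, cat in sorted(enriched_genes.items()):
            e = hypergeom_enrichment(
                len(drawn & cat), len(universe), len(cat), len(drawn)
            )
            rows.append(
                {
                    "clmr_cell": cell_a,
                    "enriched_cell": cell_b,
                    "observed": e.observed,
                    "expected": e.expected,
                    "p": e.p,
                }
            )
    return pd.DataFrame(rows)


def snps_in_regions(
    snps: Sequence[SNPRecord], regions: Sequence[tuple[str, int, int]]
) -> set[str]:
    """Ids of SNPs whose position falls within any [start, end) region."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    for ivs in by_chrom.values():
        ivs.sort()
    hits: set[str] = set()
    for s in snps:
        ivs = by_chrom.get(s.chrom)
        if not ivs:
            continue
        # regions are short and few per chrom at desk scale; linear scan is fine
        for start, end in ivs:
            if start <= s.pos < end:
                hits.add(s.snp_id)
                break
            if start > s.pos:
                break
    return hits


def gwas_snp_enrichment(
    snps: Sequence[SNPRecord],
    cdmr_regions: Sequence[tuple[str, int, int]],
    known_chroms: set[str] | None = None,
) -> dict[str, EnrichmentResult]:
    """Per-trait-class hypergeometric enrichment of SNPs inside cDMRs.

    Universe = all SNPs in the table; category = SNPs inside any cDMR;
    draws = the class's SNPs. SNPs on chromosomes absent from
    ``known_chroms`` (when given) are excluded and counted.
    """
    usable = list(snps)
    if known_chroms is not None:
        excluded = [s for s in snps if s.chrom not in known_chroms]
        usable = [s for s in snps if s.chrom in known_chroms]
        if excluded:
            import warnings

            warnings.warn(f"excluded {len(excluded)} SNPs on unknown chromosomes")
    in_cdmr = snps_in_regions(usable, cdmr_regions)
    universe_n = len(usable)
    out: dict[str, EnrichmentResult] = {}
    for trait_class in sorted({s.trait_class for s in usable}):
        class_ids = {s.snp_id for s in usable if s.trait_class == trait_class}
        out[trait_class] = hypergeom_enrichment(
            len(class_ids & in_cdmr), universe_n, len(in_cdmr), len(class_ids)
        )
    return out
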