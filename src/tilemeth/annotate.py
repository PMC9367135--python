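"""Genomic-feature and CpG-island annotation of tiled regions.

Each region receives exactly one gene-feature class with precedence
promoter > tts > exon > intron > intergenic, and one CGI class with
precedence cgi > shore > non_cgi. The promoter is the strand-aware window
``promoter_bp`` upstream of the TSS through the TSS; the TTS window is
``tts_bp`` either side of the TTS; a shore is within ``shore_bp`` of a CGI
edge. Any overlap of at least 1 bp qualifies.

For intergenic regions the nearest TSS is assigned with the distance
convention: 0 when the TSS lies inside the region, otherwise
``|closest region base - TSS| + 1`` (ties broken by lexicographically
smallest gene id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel
from .stats import EnrichmentResult, hypergeom_enrichment

FEATURE_CLASSES = ("promoter", "tts", "exon", "intron", "intergenic")
CGI_CLASSES = ("cgi", "shore", "non_cgi")


@dataclass(frozen=True)
class FeatureAnnotation:
    """One region's feature and CGI class.

    ``overlapping_gene_ids`` are genes whose span overlaps the region;
    ``feature_gene_ids`` are the genes responsible for the assigned feature
    class (the promoter's gene for a promoter region, even when the region
    lies wholly upstream of the gene body).
    """

    region_id: str
    feature_class: str
    cgi_class: str
    overlapping_gene_ids: tuple[str, ...]
    feature_gene_ids: tuple[str, ...] = ()
    nearest_gene_id: str | None = None
    nearest_tss_distance: int | None = None


def promoter_window(gene: GeneModel, promoter_bp: int, symmetric: bool = False) -> tuple[int, int]:
    """Half-open promoter interval: ``promoter_bp`` upstream of the TSS
    through the TSS base (or +/- ``promoter_bp`` when symmetric)."""
    if symmetric:
        return max(0, gene.tss - promoter_bp), gene.tss + promoter_bp + 1
    if gene.strand == "+":
        return max(0, gene.tss - promoter_bp), gene.tss + 1
    return gene.tss, gene.tss + promoter_bp + 1


def tts_window(gene: GeneModel, tts_bp: int) -> tuple[int, int]:
    return max(0, gene.tts - tts_bp), gene.tts + tts_bp + 1


def _overlaps(start: int, end: int, ivs: Sequence[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in ivs)


def nearest_tss(
    region: tuple[str, int, int], genes: Sequence[GeneModel]
) -> tuple[str, int] | None:
    """Nearest-TSS gene for a region; None if the chromosome has no genes."""
    chrom, start, end = region
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        if start <= g.tss < end:
            dist = 0
        elif g.tss < start:
            dist = start - g.tss + 1
        else:
            dist = g.tss - (end - 1) + 1
        key = (dist, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[0]


def annotate_regions(
    regions: Sequence[tuple[str, str, int, int]],
    genes: Sequence[GeneModel],
    cgis: Sequence[tuple[str, int, int]],
    promoter_bp: int = 2000,
    tts_bp: int = 1000,
    shore_bp: int = 2000,
    promoter_symmetric: bool = False,
) -> list[FeatureAnnotation]:
    """Annotate regions (id, chrom, start, end) with feature and CGI class.

    The result is independent of the ordering of ``genes`` and ``cgis``.
    """
    by_chrom: dict[str, dict[str, list]] = {}
    for g in genes:
        d = by_chrom.setdefault(g.chrom, {"prom": [], "tts": [], "exon": [], "span": []})
        d["prom"].append((*promoter_window(g, promoter_bp, promoter_symmetric), g.gene_id))
        d["tts"].append((*tts_window(g, tts_bp), g.gene_id))
        for s, e in g.exons:
            d["exon"].append((s, e, g.gene_id))
        d["span"].append((g.start, g.end, g.gene_id))
    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in cgis:
        cgi_by_chrom.setdefault(chrom, []).append((s, e))

    out: list[FeatureAnnotation] = []
    for rid, chrom, start, end in regions:
        d = by_chrom.get(chrom, {"prom": [], "tts": [], "exon": [], "span": []})
        overlapping = tuple(
            sorted({g for s, e, g in d["span"] if s < end and start < e})
        )
        prom_genes = tuple(sorted({g for s, e, g in d["prom"] if s < end and start < e}))
        tts_genes = tuple(sorted({g for s, e, g in d["tts"] if s < end and start < e}))
        exon_genes = tuple(sorted({g for s, e, g in d["exon"] if s < end and start < e}))
        if prom_genes:
            feature, feature_genes = "promoter", prom_genes
        elif tts_genes:
            feature, feature_genes = "tts", tts_genes
        elif exon_genes:
            feature, feature_genes = "exon", exon_genes
        elif overlapping:
            feature, feature_genes = "intron", overlapping
        else:
            feature, feature_genes = "intergenic", ()

        chrom_cgis = cgi_by_chrom.get(chrom, [])
        if _overlaps(start, end, chrom_cgis):
            cgi_class = "cgi"
        elif _overlaps(
            start, end, [(max(0, s - shore_bp), e + shore_bp) for s, e in chrom_cgis]
        ):
            cgi_class = "shore"
        else:
            cgi_class = "non_cgi"

        nearest_id: str | None = None
        nearest_dist: int | None = None
        if feature == "intergenic":
            hit = nearest_tss((chrom, start, end), genes)
            if hit is not None:
                nearest_id, nearest_dist = hit
        out.append(
            FeatureAnnotation(
                rid, feature, cgi_class, overlapping, feature_genes,
                nearest_id, nearest_dist,
            )
        )
    return out


def feature_enrichment(
    clmr_regions_by_cell: Mapping[str, Iterable[str]],
    all_tested_regions: Sequence[str],
    annotations: Sequence[FeatureAnnotation],
    classes: Sequence[str] = FEATURE_CLASSES,
    use_cgi: bool = False,
) -> dict[tuple[str, str], EnrichmentResult]:
    """Hypergeometric enrichment of each cell's cLMR tiles in each feature
    (or CGI) class. Universe = all tested tiles; category = tiles of the
    class; draws = the cell's cLMR tiles."""
    ann_by_region = {a.region_id: a for a in annotations}
    missing = [r for r in all_tested_regions if r not in ann_by_region]
    if missing:
        raise ValueError(f"annotations missing for regions {missing[:3]}...")
    universe = list(all_tested_regions)
    universe_n = len(universe)
    key = (lambda a: a.cgi_class) if use_cgi else (lambda a: a.feature_class)
    category_sets = {
        cls: {r for r in universe if key(ann_by_region[r]) == cls} for cls in classes
    }
    out: dict[tuple[str, str], EnrichmentResult] = {}
    for cell, regions in clmr_regions_by_cell.items():
        drawn = set(regions) & set(universe)
        for cls in classes:
            cat = category_sets[cls]
            out[(cell, cls)] = hypergeom_enrichment(
                len(drawn & cat), universe_n, len(cat), len(drawn)
            )
    return out


def enrichment_table(
    enrichments: Mapping[tuple[str, str], EnrichmentResult]
) -> pd.DataFrame:
    rows = [
        {
            "cell_type": cell,
            "class": cls,
            "observed": e.observed,
            "expected": e.expected,
            "score": e.score,
            "p": e.p,
        }
        for (cell, cls), e in sorted(enrichments.items())
    ]
    return pd.DataFrame(rows)


def region_gene_map(
    annotations: Sequence[FeatureAnnotation],
) -> dict[str, tuple[str, ...]]:
    """Region id -> associated gene ids: the feature-class genes, falling
    back to span-overlapping genes, then the nearest gene for intergenic."""
    out: dict[str, tuple[str, ...]] = {}
    for a in annotations:
        if a.feature_gene_ids:
            out[a.region_id] = a.feature_gene_ids
        elif a.overlapping_gene_ids:
            out[a.region_id] = a.overlapping_gene_ids
        elif a.nearest_gene_id is not None:
            out[a.region_id] = (a.nearest_gene_id,)
    return out
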