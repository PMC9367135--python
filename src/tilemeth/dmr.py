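"""Per-tile cell-effect testing and cLMR classification.

Each retained tile's per-sample methylation rates are fitted with the
additive two-factor model

    rate_ij = mu + cell_type_j + animal_j + e_ij

by least squares. The cell effect is tested with an extra-sum-of-squares F
statistic (full model vs the animal-only reduction); with one observation
per cell x animal this coincides with the classical balanced two-way ANOVA
F for the cell factor. Benjamini-Hochberg FDR is applied once across all
testable tiles, regions with q below the threshold are cell differentially
methylated regions (cDMRs), and a cDMR is a cell lowly methylated region
(cLMR) for a cell type when that cell's average z-score across the region's
sample rates is below -1 and its mean methylation is below 75%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import SampleMeta
from .tiling import TileMatrix

P_FLOOR = 1e-300  # keeps BH defined for exact-fit regions


@dataclass(frozen=True)
class DMRResult:
    region_id: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    q_value: float = float("nan")
    is_cdmr: bool = False
    testable: bool = True
    exact_fit: bool = False


@dataclass(frozen=True)
class CLMRCall:
    region_id: str
    cell_type: str
    mean_rate: float
    avg_z: float
    is_clmr: bool


def _design(samples: Sequence[SampleMeta], valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + cell + animal dummies) and reduced (intercept +
    animal) design matrices for the valid observations."""
    cells = sorted({s.cell_type for i, s in enumerate(samples) if valid[i]})
    animals = sorted({s.animal for i, s in enumerate(samples) if valid[i]})
    rows = [i for i in range(len(samples)) if valid[i]]
    n = len(rows)
    x_full = np.ones((n, 1 + max(len(cells) - 1, 0) + max(len(animals) - 1, 0)))
    x_red = np.ones((n, 1 + max(len(animals) - 1, 0)))
    for r, i in enumerate(rows):
        s = samples[i]
        for k, cell in enumerate(cells[1:]):
            x_full[r, 1 + k] = 1.0 if s.cell_type == cell else 0.0
        for k, animal in enumerate(animals[1:]):
            col = 1 + len(cells) - 1 + k
            x_full[r, col] = 1.0 if s.animal == animal else 0.0
            x_red[r, 1 + k] = 1.0 if s.animal == animal else 0.0
    return x_full, x_red


def _sse(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Least-squares residual sum of squares and the rank of the design."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def cell_effect_anova(
    rates, samples: Sequence[SampleMeta], region_id: str = ""
) -> DMRResult:
    """Extra-sum-of-squares F test of the cell effect for one region.

    ``rates`` is one value per sample (NaN = missing). Degenerate cases:
    constant response gives F=0, p=1; an exact additive fit (zero residual)
    gives p floored at ``P_FLOOR`` with ``exact_fit=True``; no residual
    degrees of freedom gives an untestable result (p = NaN).
    """
    y_all = np.asarray(rates, dtype=float)
    if y_all.shape != (len(samples),):
        raise ValueError("rates length does not match samples")
    valid = ~np.isnan(y_all)
    cells = {s.cell_type for i, s in enumerate(samples) if valid[i]}
    animals = {s.animal for i, s in enumerate(samples) if valid[i]}
    untestable = DMRResult(region_id, float("nan"), 0, 0, float("nan"), testable=False)
    if valid.sum() < 3 or len(cells) < 2 or len(animals) < 2:
        return untestable

    y = y_all[valid]
    x_full, x_red = _design(samples, valid)
    sse_full, rank_full = _sse(x_full, y)
    sse_red, rank_red = _sse(x_red, y)
    df_num = rank_full - rank_red
    df_den = int(valid.sum()) - rank_full
    if df_num <= 0 or df_den <= 0:
        return untestable

    sst = float(np.sum((y - y.mean()) ** 2))
    scale = max(sst, 1.0)
    if sst <= 1e-24:  # constant response
        return DMRResult(region_id, 0.0, df_num, df_den, 1.0)
    if sse_full <= 1e-12 * scale:  # exact additive fit
        return DMRResult(
            region_id, math.inf, df_num, df_den, P_FLOOR, exact_fit=True
        )
    f_stat = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
    f_stat = max(f_stat, 0.0)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return DMRResult(region_id, f_stat, df_num, df_den, min(max(p, P_FLOOR), 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are excluded from the
    batch and returned as NaN."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values outside [0,1]")
    q = np.full(p.shape, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_cdmrs(
    tiles: TileMatrix, fdr_threshold: float = 0.01
) -> list[DMRResult]:
    """Test every retained tile for a cell effect and call cDMRs at the
    given BH FDR threshold (one genome-wide batch)."""
    rates = tiles.rates
    results = [
        cell_effect_anova(rates[i], tiles.samples, region_id=rid)
        for i, rid in enumerate(tiles.regions.index)
    ]
    p = np.array([r.p_value if r.testable else np.nan for r in results])
    q = bh_fdr(p)
    out = []
    for r, qv in zip(results, q):
        is_cdmr = bool(r.testable and not math.isnan(qv) and qv < fdr_threshold)
        out.append(replace(r, q_value=float(qv), is_cdmr=is_cdmr))
    return out


def classify_clmrs(
    results: Sequence[DMRResult],
    tiles: TileMatrix,
    z_cut: float = -1.0,
    meth_cut: float = 0.75,
    level: str = "sample",
) -> list[CLMRCall]:
    """Per-cell z-score classification of cDMRs into cLMRs.

    With ``level="sample"`` (default) each sample rate at the region is
    z-scored against the mean and sample SD (n-1 denominator) of all the
    region's sample rates, and a cell's ``avg_z`` is the mean z of its
    samples; with ``level="cell"`` the nine cell-mean rates are z-scored
    directly. ``mean_rate`` is always the cell mean. A cell is flagged when
    the region is a cDMR, ``avg_z < z_cut`` and ``mean_rate < meth_cut``;
    constant regions (zero SD) yield no cLMRs.
    """
    if level not in ("sample", "cell"):
        raise ValueError("level must be 'sample' or 'cell'")
    region_ix = {rid: i for i, rid in enumerate(tiles.regions.index)}
    cells = tiles.cell_types
    cols_by_cell = {
        cell: [i for i, s in enumerate(tiles.samples) if s.cell_type == cell]
        for cell in cells
    }
    rates = tiles.rates
    calls: list[CLMRCall] = []
    for res in results:
        if not res.is_cdmr:
            continue
        i = region_ix[res.region_id]
        row = rates[i]
        cell_means = {
            cell: float(np.nanmean(row[cols])) if np.isfinite(row[cols]).any() else float("nan")
            for cell, cols in cols_by_cell.items()
        }
        if level == "sample":
            vals = row[np.isfinite(row)]
        else:
            vals = np.array([v for v in cell_means.values() if np.isfinite(v)])
        if vals.size < 2:
            continue
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        for cell in cells:
            mean_rate = cell_means[cell]
            if not np.isfinite(mean_rate):
                continue
            if sd == 0.0:
                avg_z = 0.0
                flag = False
            else:
                if level == "sample":
                    zs = (row[cols_by_cell[cell]] - mu) / sd
                    avg_z = float(np.nanmean(zs))
                else:
                    avg_z = (mean_rate - mu) / sd
                flag = bool(avg_z < z_cut and mean_rate < meth_cut)
            calls.append(CLMRCall(res.region_id, cell, mean_rate, avg_z, flag))
    return calls


def summarize_clmr_uniqueness(
    calls: Sequence[CLMRCall],
    gene_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-cell cLMR summary: totals, cell-unique counts and percentages.

    A cLMR is *unique* to a cell type when no other cell type is flagged at
    that region; a gene is unique when all its cLMRs belong to one cell
    type. Percentages are rounded to one decimal. ``gene_map`` maps region
    id to the gene ids it overlaps (may be empty or None).
    """
    flagged = [c for c in calls if c.is_clmr]
    cells_by_region: dict[str, set[str]] = {}
    for c in flagged:
        cells_by_region.setdefault(c.region_id, set()).add(c.cell_type)
    gene_map = gene_map or {}
    cells_by_gene: dict[str, set[str]] = {}
    for rid, cell_set in cells_by_region.items():
        for gene in gene_map.get(rid, ()):
            cells_by_gene.setdefault(gene, set()).update(cell_set)

    rows = []
    cell_order: dict[str, None] = {}
    for c in flagged:
        cell_order.setdefault(c.cell_type, None)
    for cell in cell_order:
        regions = {c.region_id for c in flagged if c.cell_type == cell}
        n = len(regions)
        n_unique = sum(1 for r in regions if cells_by_region[r] == {cell})
        genes = {g for r in regions for g in gene_map.get(r, ())}
        n_genes = len(genes)
        n_unique_genes = sum(1 for g in genes if cells_by_gene[g] == {cell})
        rows.append(
            {
                "cell_type": cell,
                "n_clmrs": n,
                "n_unique": n_unique,
                "pct_unique": round(100.0 * n_unique / n, 1) if n else float("nan"),
                "n_genes": n_genes,
                "n_unique_genes": n_unique_genes,
                "pct_unique_genes": round(100.0 * n_unique_genes / n_genes, 1)
                if n_genes
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
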