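"""Genome tiling: pool CpG counts into fixed non-overlapping windows.

Regional methylation is the coverage-weighted pooled rate
``sum(n_meth) / sum(n_total)`` over a tile's CpGs — not the mean of per-CpG
rates — matching how regional rates are computed by standard WGBS tiling
tools. The study-design coverage filter (tile coverage > 25 in at least 7
cell types in every animal) is applied per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CpGRecord, SampleMeta, open_text


def region_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class TileMatrix:
    """Per-region, per-sample pooled CpG counts.

    ``regions`` is a DataFrame indexed by region id with columns chrom,
    start, end, n_cpg (tiles in genome order); ``n_meth``/``n_total`` are
    (n_regions, n_samples) integer arrays aligned with ``samples``.
    ``low_coverage`` flags cells whose pooled total failed the coverage
    cutoff in a retained tile (set by :func:`apply_coverage_filter`).
    """

    regions: pd.DataFrame
    samples: list[SampleMeta]
    n_meth: np.ndarray
    n_total: np.ndarray
    tile_size: int = 1000
    low_coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_r, n_s = len(self.regions), len(self.samples)
        if self.n_meth.shape != (n_r, n_s) or self.n_total.shape != (n_r, n_s):
            raise ValueError("count matrices do not match regions x samples")
        if (self.n_meth > self.n_total).any():
            raise ValueError("n_meth exceeds n_total")

    @property
    def rates(self) -> np.ndarray:
        """Pooled methylation rate per (region, sample); NaN where no coverage."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_meth / np.maximum(self.n_total, 1), np.nan)

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cell_type, None)
        return list(seen)

    @property
    def animals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.animal, None)
        return list(seen)

    def cell_mean_rates(self) -> np.ndarray:
        """(n_regions, n_cell_types) mean of per-sample rates within cell type."""
        cells = self.cell_types
        rates = self.rates
        out = np.full((len(self.regions), len(cells)), np.nan)
        for j, cell in enumerate(cells):
            cols = [i for i, s in enumerate(self.samples) if s.cell_type == cell]
            with np.errstate(invalid="ignore"):
                out[:, j] = np.nanmean(rates[:, cols], axis=1)
        return out

    def subset(self, keep: np.ndarray) -> "TileMatrix":
        return TileMatrix(
            self.regions.iloc[keep].copy(),
            list(self.samples),
            self.n_meth[keep],
            self.n_total[keep],
            self.tile_size,
            None if self.low_coverage is None else self.low_coverage[keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open_text(path, "wt") as fh:
            head = ["region_id", "chrom", "start", "end", "n_cpg"]
            for s in self.samples:
                head += [f"{s.sample_id}.n_meth", f"{s.sample_id}.n_total", f"{s.sample_id}.rate"]
            fh.write("\t".join(head) + "\n")
            rates = self.rates
            for i, (rid, row) in enumerate(self.regions.iterrows()):
                vals = [rid, row.chrom, str(row.start), str(row.end), str(row.n_cpg)]
                for j in range(len(self.samples)):
                    vals += [str(self.n_meth[i, j]), str(self.n_total[i, j]), repr(float(rates[i, j]))]
                fh.write("\t".join(vals) + "\n")


@dataclass(frozen=True)
class FilterSpec:
    """Study-design coverage filter: a tile is kept iff for every animal at
    least ``min_cell_types`` cell types have pooled coverage strictly greater
    than ``min_coverage``."""

    min_coverage: int = 25
    min_cell_types: int = 7
    per_animal: bool = True


def tile_counts(
    reports: Mapping[str, Iterable[CpGRecord]],
    samples: Sequence[SampleMeta],
    tile_size: int = 1000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> TileMatrix:
    """Aggregate per-sample CpG records into non-overlapping tiles.

    Tile boundaries sit at multiples of ``tile_size`` from coordinate 0.
    Tiles with no CpG in any sample are excluded. ``reports`` maps sample id
    to an iterable of (0-based) CpG records; record order is irrelevant.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    sample_ids = [s.sample_id for s in samples]
    if set(reports) - set(sample_ids):
        raise ValueError("reports contain samples absent from metadata")
    idx = {sid: j for j, sid in enumerate(sample_ids)}

    counts: dict[tuple[str, int], np.ndarray] = {}
    cpg_pos: dict[tuple[str, int], set[int]] = {}
    for sid, records in reports.items():
        j = idx[sid]
        for rec in records:
            if chrom_lengths is not None:
                length = chrom_lengths.get(rec.chrom)
                if length is not None and rec.pos >= length:
                    raise ValueError(
                        f"record at {rec.chrom}:{rec.pos} beyond chromosome length {length}"
                    )
            key = (rec.chrom, (rec.pos // tile_size) * tile_size)
            arr = counts.get(key)
            if arr is None:
                arr = np.zeros((2, len(samples)), dtype=np.int64)
                counts[key] = arr
                cpg_pos[key] = set()
            arr[0, j] += rec.n_meth
            arr[1, j] += rec.n_total
            cpg_pos[key].add(rec.pos)

    keys = sorted(counts)
    n_meth = np.zeros((len(keys), len(samples)), dtype=np.int64)
    n_total = np.zeros_like(n_meth)
    rows = []
    for i, key in enumerate(keys):
        chrom, start = key
        end = start + tile_size
        if chrom_lengths is not None and chrom in chrom_lengths:
            end = min(end, chrom_lengths[chrom])  # final partial tile kept
        n_meth[i] = counts[key][0]
        n_total[i] = counts[key][1]
        rows.append((region_id(chrom, start, end), chrom, start, end, len(cpg_pos[key])))
    regions = pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "n_cpg"]
    ).set_index("region_id")
    return TileMatrix(regions, list(samples), n_meth, n_total, tile_size)


def apply_coverage_filter(tiles: TileMatrix, spec: FilterSpec = FilterSpec()) -> TileMatrix:
    """Retain tiles passing the per-animal cell-coverage rule.

    A cell type counts as covered in an animal when the pooled ``n_total`` of
    its (cell, animal) sample is strictly greater than ``spec.min_coverage``.
    With ``per_animal=False`` coverage is summed across animals per cell
    type. Surviving low-coverage cells stay defined but are flagged in
    ``low_coverage``.
    """
    cells = tiles.cell_types
    if spec.min_cell_types > len(cells):
        raise ValueError("min_cell_types exceeds number of cell types")
    covered = tiles.n_total > spec.min_coverage  # (R, S)
    if spec.per_animal:
        keep = np.ones(len(tiles.regions), dtype=bool)
        for animal in tiles.animals:
            cols_by_cell = [
                [i for i, s in enumerate(tiles.samples)
                 if s.animal == animal and s.cell_type == cell]
                for cell in cells
            ]
            n_cov = np.zeros(len(tiles.regions), dtype=int)
            for cols in cols_by_cell:
                if cols:
                    n_cov += covered[:, cols].any(axis=1)
            keep &= n_cov >= spec.min_cell_types
    else:
        n_cov = np.zeros(len(tiles.regions), dtype=int)
        for cell in cells:
            cols = [i for i, s in enumerate(tiles.samples) if s.cell_type == cell]
            cell_total = tiles.n_total[:, cols].sum(axis=1)
            n_cov += cell_total > spec.min_coverage
        keep = n_cov >= spec.min_cell_types
    out = tiles.subset(np.flatnonzero(keep))
    out.low_coverage = ~(out.n_total > spec.min_coverage)
    return out


def global_methylation(reports: Mapping[str, Iterable[CpGRecord]]) -> dict[str, float]:
    """Global CpG methylation percentage per sample:
    ``100 * sum(n_meth) / sum(n_total)`` over all the sample's CpGs."""
    out: dict[str, float] = {}
    for sid, records in reports.items():
        n_meth = 0
        n_total = 0
        for rec in records:
            n_meth += rec.n_meth
            n_total += rec.n_total
        if n_total == 0:
            raise ValueError(f"global_methylation: sample {sid} has zero coverage")
        out[sid] = 100.0 * n_meth / n_total
    return out


def cell_global_methylation(
    per_sample: Mapping[str, float], samples: Sequence[SampleMeta]
) -> dict[str, float]:
    """Per-cell global methylation: mean of that cell's animal samples."""
    by_cell: dict[str, list[float]] = {}
    for s in samples:
        if s.sample_id in per_sample:
            by_cell.setdefault(s.cell_type, []).append(per_sample[s.sample_id])
    return {cell: float(np.mean(v)) for cell, v in by_cell.items()}
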