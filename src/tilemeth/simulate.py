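"""Synthetic study generator: methylomes, expression, annotation, motifs.

Emulates the study design — nine sorted immune-cell populations from two
animals — on a small genome with known ground truth, so every downstream
stage is testable without external data. Per-CpG counts are binomial draws
around per-tile baseline rates (Beta-distributed), with a per-animal offset
added on the logit scale and cell-specific hypomethylation planted at chosen
tiles. Expression, gene models, CpG islands, GWAS SNPs, motif carrier
sequences and the PWM set are all derived from the same ground-truth layout
so that planted signals propagate coherently through the pipeline.

The whole genome layout (genes, CGIs, planted tiles, links) is decided in
:func:`simulate_methylomes` and recorded on :class:`GroundTruth`;
:func:`simulate_expression` and :func:`simulate_annotation_and_snps` are
deterministic functions of (config, truth). Every stage draws from an
independent child seed of ``config.seed``, and a fixed seed reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CELL_TYPES,
    CpGRecord,
    GeneModel,
    PWM,
    SampleMeta,
    SNPRecord,
    write_bed3,
    write_cpg_report,
    write_fasta,
    write_gene_bed12,
    write_meme_pwms,
    write_snp_table,
)
from .tiling import region_id


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the package's standing study conditions: a 2 x 1 Mb genome
    (2,000 tiles), nine cell types x two animals, Poisson(30) per-CpG depth,
    CpG spacing ~Exp(100 bp) outside CpG islands (10x denser inside), and
    Beta(8, 2) baseline tile methylation (mean 0.8, matching the ~80-84%
    global methylation typical of sorted immune cells).
    """

    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    cpg_spacing_mean_bp: float = 100.0
    cell_types: tuple[str, ...] = CELL_TYPES
    n_animals: int = 2
    mean_depth: float = 30.0
    baseline_meth_alpha: float = 8.0
    baseline_meth_beta: float = 2.0
    n_dmr_planted: int = 80
    dmr_effect: float = 0.3
    animal_effect_sd: float = 0.1
    frac_genes_correlated: float = 0.3
    seed: int = 0
    # layout parameters
    tile_size: int = 1000
    n_genes: int = 60
    n_cgis: int = 30
    cgi_length_bp: int = 800
    n_snps: int = 200
    immune_snp_frac: float = 0.25
    snp_in_cdmr_frac: float = 0.6
    # expression parameters
    expression_slope: float = 8.0
    expression_noise_sd: float = 0.25
    # motif parameters
    motif_width: int = 8
    n_decoy_motifs: int = 10
    motif_carrier_rate: float = 0.6

    def validate(self) -> None:
        if min(self.n_chroms, self.chrom_length_bp, self.tile_size) <= 0:
            raise ValueError("counts must be positive")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2 (cell and animal effects "
                             "are not separable with a single animal)")
        if not 0.0 < self.dmr_effect <= 1.0:
            raise ValueError("dmr_effect must be in (0, 1]")
        if self.animal_effect_sd < 0:
            raise ValueError("animal_effect_sd must be non-negative")
        if not 0.0 <= self.frac_genes_correlated <= 1.0:
            raise ValueError("frac_genes_correlated must be in [0, 1]")
        if self.cpg_spacing_mean_bp <= 0 or self.mean_depth <= 0:
            raise ValueError("cpg_spacing_mean_bp and mean_depth must be positive")
        if len(self.cell_types) < 2:
            raise ValueError("need at least two cell types")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}

    @property
    def animals(self) -> list[str]:
        return [f"A{i + 1}" for i in range(self.n_animals)]

    def sample_sheet(self) -> list[SampleMeta]:
        return [
            SampleMeta(f"{cell}_{animal}", cell, animal)
            for cell in self.cell_types
            for animal in self.animals
        ]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass(frozen=True)
class PlantedDMR:
    region_id: str
    chrom: str
    start: int
    end: int
    target_cell: str
    baseline_rate: float
    effect: float


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream verification."""

    cell_types: tuple[str, ...]
    tile_size: int
    chrom_lengths: dict[str, int]
    tiles: list[tuple[str, int, int]]
    baseline_rates: np.ndarray  # (n_tiles,)
    true_rates: np.ndarray  # (n_tiles, n_cells): expected rate before animal offset
    animal_offsets: dict[str, float]  # logit-scale
    planted_dmrs: list[PlantedDMR]
    cgi_intervals: list[tuple[str, int, int]]
    genes: list[GeneModel]
    gene_region_links: list[tuple[str, str, int]]  # (gene_id, region_id, sign)
    planted_snps_in_dmrs: list[str] = field(default_factory=list)
    planted_motif_id: str = ""
    motif_carrier_ids: list[str] = field(default_factory=list)

    def tile_index(self) -> dict[str, int]:
        return {
            region_id(c, s, e): i for i, (c, s, e) in enumerate(self.tiles)
        }

    def planted_region_ids(self) -> set[str]:
        return {p.region_id for p in self.planted_dmrs}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cell_types": list(self.cell_types),
            "tile_size": self.tile_size,
            "chrom_lengths": self.chrom_lengths,
            "animal_offsets": self.animal_offsets,
            "planted_dmrs": [asdict(p) for p in self.planted_dmrs],
            "cgi_intervals": [list(iv) for iv in self.cgi_intervals],
            "gene_region_links": [list(l) for l in self.gene_region_links],
            "planted_snps_in_dmrs": self.planted_snps_in_dmrs,
            "planted_motif_id": self.planted_motif_id,
            "motif_carrier_ids": self.motif_carrier_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Non-overlapping gene models with tile-aligned TSSs, alternating strands.

    The TSS sits on a tile boundary so a linked gene's promoter window
    covers whole tiles; gene span is 5 kb with three exons.
    """
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    slot = config.chrom_length_bp // per_chrom
    gene_len = 5000
    if slot < 2 * gene_len + 3 * config.tile_size:
        raise ValueError("genome too small for requested gene count")
    genes: list[GeneModel] = []
    gi = 0
    for chrom in config.chrom_names:
        for k in range(per_chrom):
            if gi >= config.n_genes:
                break
            strand = "+" if gi % 2 == 0 else "-"
            anchor = k * slot + 3 * config.tile_size
            anchor = (anchor // config.tile_size) * config.tile_size
            if strand == "+":
                start, end = anchor, anchor + gene_len
            else:
                end = anchor  # TSS at end-1; keep it just left of the boundary
                start = end - gene_len
            exons = (
                (start, start + 400),
                (start + 1800, start + 2600),
                (end - 500, end),
            )
            genes.append(GeneModel(f"G{gi:04d}", chrom, strand, start, end, exons))
            gi += 1
    return genes


def _promoter_tile(gene: GeneModel, tile_size: int) -> tuple[str, int, int]:
    """The tile immediately upstream of the TSS (fully inside the promoter).

    Genes are laid out with the TSS-side boundary tile-aligned, so the
    upstream tile is exact: ``[tss - tile_size, tss)`` on the plus strand and
    ``[end, end + tile_size)`` on the minus strand.
    """
    start = gene.tss - tile_size if gene.strand == "+" else gene.end
    return (gene.chrom, start, start + tile_size)


def _place_cgis(
    config: SimConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """CGIs at a subset of gene TSSs plus random intergenic spots."""
    cgis: list[tuple[str, int, int]] = []
    n_at_tss = min(config.n_cgis // 2, len(genes))
    for g in genes[:n_at_tss]:
        center = g.tss
        start = max(0, center - config.cgi_length_bp // 2)
        cgis.append((g.chrom, start, start + config.cgi_length_bp))
    attempts = 0
    while len(cgis) < config.n_cgis and attempts < 10_000:
        attempts += 1
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length_bp - config.cgi_length_bp))
        iv = (chrom, start, start + config.cgi_length_bp)
        if all(
            not (c == chrom and s < iv[2] and iv[1] < e) for c, s, e in cgis
        ):
            cgis.append(iv)
    if len(cgis) < config.n_cgis:
        raise ValueError("genome too small for requested CGI count")
    return sorted(cgis)


def _cpg_positions(
    config: SimConfig, cgis: Sequence[tuple[str, int, int]], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """CpG coordinates per chromosome: exponential spacing with mean
    ``cpg_spacing_mean_bp`` outside CGIs and one tenth of that inside."""
    out: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        chrom_cgis = sorted((s, e) for c, s, e in cgis if c == chrom)
        positions: list[int] = []
        pos = int(rng.integers(2, 50))
        ci = 0
        length = config.chrom_lengths[chrom]
        while pos < length - 1:
            while ci < len(chrom_cgis) and chrom_cgis[ci][1] <= pos:
                ci += 1
            inside = ci < len(chrom_cgis) and chrom_cgis[ci][0] <= pos
            mean = config.cpg_spacing_mean_bp / 10.0 if inside else config.cpg_spacing_mean_bp
            positions.append(pos)
            pos += max(2, int(round(rng.exponential(mean))))
        out[chrom] = np.asarray(positions, dtype=np.int64)
    return out


def _tiles(config: SimConfig) -> list[tuple[str, int, int]]:
    tiles = []
    for chrom in config.chrom_names:
        length = config.chrom_lengths[chrom]
        for start in range(0, length, config.tile_size):
            tiles.append((chrom, start, min(start + config.tile_size, length)))
    return tiles


def simulate_methylomes(
    config: SimConfig,
) -> tuple[dict[str, list[CpGRecord]], GroundTruth]:
    """Generate one CpG report per (cell type x animal) sample plus truth.

    Per CpG: depth ~ Poisson(mean_depth) and methylated count ~
    Binomial(depth, rate), where the rate is the tile's cell-specific true
    rate shifted by the animal's logit offset. Planted cDMR tiles have the
    target cell's rate reduced by ``dmr_effect``; planting sites are chosen
    among tiles whose baseline leaves the depressed rate inside [0, 1].
    """
    config.validate()
    rng = config.rng(1)

    genes = _place_genes(config, rng)
    cgis = _place_cgis(config, genes, rng)
    cpgs = _cpg_positions(config, cgis, rng)
    tiles = _tiles(config)
    tile_ix = {region_id(c, s, e): i for i, (c, s, e) in enumerate(tiles)}
    n_tiles = len(tiles)
    n_cells = len(config.cell_types)

    baseline = np.clip(
        rng.beta(config.baseline_meth_alpha, config.baseline_meth_beta, size=n_tiles),
        0.01,
        0.99,
    )

    # -- choose planted tiles: linked genes' promoter tiles first, then others
    n_linked = int(round(config.frac_genes_correlated * len(genes)))
    n_linked = min(n_linked, config.n_dmr_planted)
    linked_genes = list(rng.choice(len(genes), size=n_linked, replace=False)) if n_linked else []
    planted_ids: list[str] = []
    links: list[tuple[str, str, int]] = []
    for gidx in linked_genes:
        g = genes[int(gidx)]
        chrom, start, end = _promoter_tile(g, config.tile_size)
        rid = region_id(chrom, start, end)
        if rid not in tile_ix or rid in planted_ids:
            continue
        planted_ids.append(rid)
        links.append((g.gene_id, rid, -1))

    forbidden = set(planted_ids)
    # keep gene promoters un-planted unless linked, so background promoter
    # tiles stay null
    for g in genes:
        chrom, start, end = _promoter_tile(g, config.tile_size)
        forbidden.add(region_id(chrom, start, end))
    candidates = [
        rid
        for rid, i in tile_ix.items()
        if rid not in forbidden and baseline[i] >= config.dmr_effect + 0.02
    ]
    n_extra = config.n_dmr_planted - len(planted_ids)
    if n_extra > len(candidates):
        raise ValueError("not enough eligible tiles for requested n_dmr_planted")
    if n_extra > 0:
        planted_ids += list(rng.choice(candidates, size=n_extra, replace=False))

    # baselines at planted tiles must leave the depressed rate inside [0, 1]
    lo = config.dmr_effect + 0.02
    for rid in planted_ids:
        i = tile_ix[rid]
        if baseline[i] < lo:
            baseline[i] = float(rng.uniform(lo, 0.99))

    targets = [
        config.cell_types[int(t)]
        for t in rng.integers(0, n_cells, size=len(planted_ids))
    ]
    true_rates = np.repeat(baseline[:, None], n_cells, axis=1)
    planted: list[PlantedDMR] = []
    for rid, target in zip(planted_ids, targets):
        i = tile_ix[rid]
        j = config.cell_types.index(target)
        if baseline[i] - config.dmr_effect < -1e-9:
            raise ValueError("dmr_effect drives a planted rate below 0")
        true_rates[i, j] = baseline[i] - config.dmr_effect
        chrom, start, end = tiles[i]
        planted.append(
            PlantedDMR(rid, chrom, start, end, target, float(baseline[i]), config.dmr_effect)
        )

    offsets = {
        a: float(rng.normal(0.0, config.animal_effect_sd)) if config.animal_effect_sd > 0 else 0.0
        for a in config.animals
    }

    # -- draw counts
    reports: dict[str, list[CpGRecord]] = {}
    for cell_j, cell in enumerate(config.cell_types):
        for animal in config.animals:
            sid = f"{cell}_{animal}"
            records: list[CpGRecord] = []
            for chrom in config.chrom_names:
                pos = cpgs[chrom]
                tile_of = pos // config.tile_size
                base_row = (
                    tile_ix[region_id(chrom, 0, min(config.tile_size, config.chrom_lengths[chrom]))]
                )
                rates = true_rates[base_row + tile_of, cell_j]
                if offsets[animal] != 0.0:
                    rates = _expit(_logit(rates) + offsets[animal])
                rates = np.clip(rates, 0.0, 1.0)
                depth = rng.poisson(config.mean_depth, size=pos.size)
                meth = rng.binomial(depth, rates)
                records.extend(
                    CpGRecord(chrom, int(p), "+", int(m), int(d - m))
                    for p, d, m in zip(pos, depth, meth)
                )
            reports[sid] = records

    truth = GroundTruth(
        cell_types=config.cell_types,
        tile_size=config.tile_size,
        chrom_lengths=dict(config.chrom_lengths),
        tiles=tiles,
        baseline_rates=baseline,
        true_rates=true_rates,
        animal_offsets=offsets,
        planted_dmrs=planted,
        cgi_intervals=cgis,
        genes=genes,
        gene_region_links=links,
    )
    return reports, truth


def simulate_expression(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM table (gene x sample) plus the expression-enriched gene table.

    Linked genes' log2 abundance is a monotone function of the linked
    tile's true per-cell methylation (sign -1: decreasing), with lognormal
    replicate noise; unlinked genes have flat cell means. The enriched table
    lists genes whose noise-free log2 fold change of one cell versus the
    mean of the others exceeds 1, labelled with that cell type.
    """
    rng = config.rng(2)
    tile_ix = truth.tile_index()
    gene_ids = [g.gene_id for g in truth.genes]
    linked: dict[str, tuple[str, int]] = {}
    for gene_id, rid, sign in truth.gene_region_links:
        if gene_id not in gene_ids:
            raise ValueError(f"link references unknown gene id {gene_id!r}")
        linked[gene_id] = (rid, sign)

    cells = list(truth.cell_types)
    n_cells = len(cells)
    base_log2 = rng.normal(5.0, 1.5, size=len(gene_ids))
    cell_means = np.repeat(base_log2[:, None], n_cells, axis=1)
    for gi, gene_id in enumerate(gene_ids):
        if gene_id in linked:
            rid, sign = linked[gene_id]
            m = truth.true_rates[tile_ix[rid]]
            cell_means[gi] += sign * config.expression_slope * (m - m.mean())

    samples = [f"{cell}_{a}" for cell in cells for a in config.animals]
    noise = (
        rng.normal(0.0, config.expression_noise_sd, size=(len(gene_ids), len(samples)))
        if config.expression_noise_sd > 0
        else np.zeros((len(gene_ids), len(samples)))
    )
    log2tpm = np.repeat(cell_means, config.n_animals, axis=1) + noise
    tpm = pd.DataFrame(2.0 ** log2tpm, index=gene_ids, columns=samples)
    tpm.index.name = "gene"

    rows = []
    for gi, gene_id in enumerate(gene_ids):
        for j, cell in enumerate(cells):
            others = np.delete(cell_means[gi], j)
            log2fc = float(cell_means[gi, j] - others.mean())
            if log2fc > 1.0:
                rows.append(
                    {"gene": gene_id, "cell_type": cell, "log2fc": round(log2fc, 4),
                     "fdr": 1e-6}
                )
    enriched = pd.DataFrame(rows, columns=["gene", "cell_type", "log2fc", "fdr"])
    return tpm, enriched


@dataclass
class SimAnnotations:
    genes: list[GeneModel]
    cgis: list[tuple[str, int, int]]
    snps: list[SNPRecord]
    positive_seqs: dict[str, str]
    control_seqs: dict[str, str]
    pwms: list[PWM]


def _random_pwm(width: int, rng: np.random.Generator, peak: float = 0.85) -> tuple:
    cols = []
    for _ in range(width):
        j = int(rng.integers(4))
        col = [(1.0 - peak) / 3.0] * 4
        col[j] = peak
        cols.append(tuple(col))
    return tuple(cols)


def simulate_annotation_and_snps(
    config: SimConfig, truth: GroundTruth
) -> SimAnnotations:
    """Materialize gene/CGI annotation, the GWAS SNP table, tile sequences
    with the planted motif consensus embedded, and the PWM set.

    Mutates ``truth`` to record planted SNP ids and motif carrier ids.
    """
    rng = config.rng(3)
    planted = truth.planted_dmrs

    # -- SNPs
    snps: list[SNPRecord] = []
    n_immune = int(round(config.immune_snp_frac * config.n_snps))
    n_in_cdmr = int(round(config.snp_in_cdmr_frac * n_immune))
    if n_in_cdmr > 0 and not planted:
        raise ValueError("cannot plant SNPs inside cDMRs: none were planted")
    planted_ids: list[str] = []
    for i in range(config.n_snps):
        snp_id = f"rs{i:05d}"
        if i < n_in_cdmr:
            p = planted[int(rng.integers(len(planted)))]
            pos = int(rng.integers(p.start, p.end))
            snps.append(SNPRecord(snp_id, p.chrom, pos, "immune capacity"))
            planted_ids.append(snp_id)
        else:
            trait_class = "immune capacity" if i < n_immune else "other"
            chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
            pos = int(rng.integers(0, config.chrom_lengths[chrom]))
            snps.append(SNPRecord(snp_id, chrom, pos, trait_class))
    truth.planted_snps_in_dmrs = planted_ids

    # -- PWMs: one planted + decoys
    planted_pwm = PWM("PLANTED", _random_pwm(config.motif_width, rng))
    decoys = [
        PWM(f"DECOY{k:02d}", _random_pwm(config.motif_width, rng))
        for k in range(config.n_decoy_motifs)
    ]
    pwms = [planted_pwm] + decoys
    truth.planted_motif_id = planted_pwm.motif_id

    # -- sequences: positives = planted tiles, controls = random other tiles
    def random_seq(length: int) -> str:
        return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))

    positive: dict[str, str] = {}
    carriers: list[str] = []
    consensus = planted_pwm.consensus
    for p in planted:
        seq = random_seq(p.end - p.start)
        if rng.random() < config.motif_carrier_rate:
            off = int(rng.integers(0, len(seq) - len(consensus)))
            seq = seq[:off] + consensus + seq[off + len(consensus):]
            carriers.append(p.region_id)
        positive[p.region_id] = seq
    truth.motif_carrier_ids = carriers

    planted_set = truth.planted_region_ids()
    others = [t for t in truth.tiles if region_id(*t) not in planted_set]
    picks = rng.choice(len(others), size=min(len(planted), len(others)), replace=False)
    control = {
        region_id(*others[int(i)]): random_seq(
            others[int(i)][2] - others[int(i)][1]
        )
        for i in picks
    }

    return SimAnnotations(
        genes=list(truth.genes),
        cgis=list(truth.cgi_intervals),
        snps=snps,
        positive_seqs=positive,
        control_seqs=control,
        pwms=pwms,
    )


def write_simulation(
    config: SimConfig,
    outdir: str | Path,
    reports: dict[str, list[CpGRecord]],
    truth: GroundTruth,
    tpm: pd.DataFrame | None = None,
    enriched: pd.DataFrame | None = None,
    ann: SimAnnotations | None = None,
) -> dict[str, str]:
    """Write all simulated inputs to a directory; returns a path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sid, records in reports.items():
        p = outdir / f"{sid}.cpg_report.txt"
        write_cpg_report(records, p)
        paths[f"cpg_report:{sid}"] = str(p)
    sheet = outdir / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tcell_type\tanimal\n")
        for s in config.sample_sheet():
            fh.write(f"{s.sample_id}\t{s.cell_type}\t{s.animal}\n")
    paths["sample_sheet"] = str(sheet)
    truth.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    if tpm is not None:
        tpm.to_csv(outdir / "tpm.tsv", sep="\t")
        paths["tpm"] = str(outdir / "tpm.tsv")
    if enriched is not None:
        enriched.to_csv(outdir / "enriched_genes.tsv", sep="\t", index=False)
        paths["enriched_genes"] = str(outdir / "enriched_genes.tsv")
    if ann is not None:
        write_gene_bed12(ann.genes, outdir / "genes.bed")
        write_bed3(ann.cgis, outdir / "cgi.bed")
        write_snp_table(ann.snps, outdir / "snps.tsv")
        write_fasta(ann.positive_seqs, outdir / "clmr_seqs.fa")
        write_fasta(ann.control_seqs, outdir / "control_seqs.fa")
        write_meme_pwms(ann.pwms, outdir / "motifs.meme")
        paths.update(
            genes=str(outdir / "genes.bed"),
            cgi=str(outdir / "cgi.bed"),
            snps=str(outdir / "snps.tsv"),
            clmr_seqs=str(outdir / "clmr_seqs.fa"),
            control_seqs=str(outdir / "control_seqs.fa"),
            motifs=str(outdir / "motifs.meme"),
        )
    return paths
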