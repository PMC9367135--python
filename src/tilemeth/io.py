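"""Readers and writers for every file format the pipeline touches.

All genomic coordinates are held 0-based half-open in memory. Formats that
are 1-based on disk (Bismark-style CpG reports, SNP tables) are converted on
read (``pos - 1``) and restored on write. All text readers and writers are
gzip-transparent: a path ending in ``.gz`` is compressed.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

CELL_TYPES = (
    "CD4T",
    "SWC6gdT",
    "Myeloid",
    "CD8T",
    "Neut",
    "CD21nB",
    "CD21pB",
    "NK",
    "CD4CD8T",
)
"""The nine sorted immune-cell populations of the study design."""


class CpGRecord(NamedTuple):
    """One CpG's methylated/unmethylated read counts in one sample.

    ``pos`` is the 0-based coordinate of the cytosine (the plus-strand C of
    the CpG dinucleotide after strand merging).
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int

    @property
    def n_total(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one WGBS library: which cell population, which animal."""

    sample_id: str
    cell_type: str
    animal: str


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene model with strand-aware TSS/TTS.

    ``start``/``end`` are the 0-based half-open gene span; ``exons`` are
    non-overlapping half-open intervals within the span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span for gene {self.gene_id}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"bad exons for gene {self.gene_id}")
            prev = e

    @property
    def tss(self) -> int:
        """5' end of the gene (0-based base coordinate), respecting strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """3' end of the gene (0-based base coordinate), respecting strand."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class SNPRecord:
    snp_id: str
    chrom: str
    pos: int  # 0-based
    trait_class: str
    trait: str = ""


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities (A,C,G,T)."""

    motif_id: str
    matrix: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.matrix) == 0:
            raise ValueError(f"empty PWM {self.motif_id}")
        for i, col in enumerate(self.matrix):
            if len(col) != 4 or any(p < 0 for p in col):
                raise ValueError(f"PWM {self.motif_id} column {i} malformed")
            if abs(sum(col) - 1.0) > 1e-6:
                raise ValueError(
                    f"PWM {self.motif_id} column {i} sums to {sum(col)}, not 1"
                )

    @property
    def width(self) -> int:
        return len(self.matrix)

    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[int(np.argmax(col))] for col in self.matrix)


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# CpG reports (Bismark cytosine-report dialect)
# ---------------------------------------------------------------------------

def read_cpg_report(
    path: str | Path, strand_policy: str = "merge"
) -> Iterator[CpGRecord]:
    """Stream CpG records from a Bismark-style cytosine report.

    Columns: chrom, 1-based position, strand, count_methylated,
    count_unmethylated, context. Only ``CpG`` context lines are kept; other
    contexts are skipped and counted in a single summary warning.

    With ``strand_policy="merge"`` (the default), plus/minus records at the
    same CpG dinucleotide (minus position = plus position + 1) are summed
    into one plus-strand record; with ``"keep"`` records pass through
    unchanged (still 0-based).
    """
    if strand_policy not in ("merge", "keep"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    yield from _merge_or_keep(_parse_cpg_lines(path), strand_policy)


def _parse_cpg_lines(path: str | Path) -> Iterator[CpGRecord]:
    skipped = 0
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            chrom, pos_s, strand, meth_s, unmeth_s = fields[:5]
            context = fields[5] if len(fields) > 5 else "CpG"
            if context != "CpG":
                skipped += 1
                continue
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: negative count on line {lineno}")
            if pos < 1:
                raise ValueError(f"{path}: position < 1 on line {lineno}")
            if strand not in "+-":
                raise ValueError(f"{path}: bad strand on line {lineno}")
            yield CpGRecord(chrom, pos - 1, strand, n_meth, n_unmeth)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-CpG context lines", stacklevel=3)


def _merge_or_keep(
    records: Iterable[CpGRecord], strand_policy: str
) -> Iterator[CpGRecord]:
    if strand_policy == "keep":
        yield from records
        return
    pending: CpGRecord | None = None  # plus-strand record awaiting its partner
    for rec in records:
        if rec.strand == "+":
            if pending is not None:
                yield pending
            pending = rec
        else:
            plus_pos = rec.pos - 1
            if (
                pending is not None
                and pending.chrom == rec.chrom
                and pending.pos == plus_pos
            ):
                yield CpGRecord(
                    rec.chrom,
                    plus_pos,
                    "+",
                    pending.n_meth + rec.n_meth,
                    pending.n_unmeth + rec.n_unmeth,
                )
                pending = None
            else:
                if pending is not None:
                    yield pending
                    pending = None
                yield CpGRecord(rec.chrom, plus_pos, "+", rec.n_meth, rec.n_unmeth)
    if pending is not None:
        yield pending


def write_cpg_report(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write records in the cytosine-report dialect (1-based positions)."""
    with open_text(path, "wt") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.strand}\t"
                f"{rec.n_meth}\t{rec.n_unmeth}\tCpG\n"
            )


def conversion_efficiency(lambda_records: Iterable[CpGRecord]) -> float:
    """Bisulfite conversion efficiency from unmethylated spike-in counts.

    Returns ``100 - 100 * sum(n_meth) / sum(n_meth + n_unmeth)`` over all
    cytosines aligned to the spike-in (lambda phage) genome: the percentage
    of cytosines successfully converted.
    """
    n_meth = 0
    n_total = 0
    for rec in lambda_records:
        n_meth += rec.n_meth
        n_total += rec.n_total
    if n_total == 0:
        raise ValueError("conversion_efficiency: zero total spike-in coverage")
    return 100.0 - 100.0 * n_meth / n_total


# ---------------------------------------------------------------------------
# BED / TSV / MEME readers
# ---------------------------------------------------------------------------

def read_gene_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd ignored)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            if start < 0 or end <= start:
                raise ValueError(f"{path}: line {lineno}: bad coordinates")
            if name in seen:
                raise ValueError(f"{path}: duplicate gene id {name!r}")
            seen.add(name)
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def write_gene_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_cgi_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read CpG-island intervals from BED3 (0-based half-open)."""
    out: list[tuple[str, int, int]] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            if start < 0 or end <= start:
                raise ValueError(f"{path}: line {lineno}: bad interval")
            out.append((f[0], start, end))
    return out


def write_bed3(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """Read a SNP table: TSV with header id, chrom, pos_1based, trait_class[, trait]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "chrom", "pos_1based", "trait_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        pos = int(row.pos_1based)
        if pos < 1:
            raise ValueError(f"{path}: SNP {row.id}: position < 1")
        out.append(
            SNPRecord(
                row.id,
                row.chrom,
                pos - 1,
                row.trait_class,
                getattr(row, "trait", "") or "",
            )
        )
    return out


def write_snp_table(snps: Iterable[SNPRecord], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        fh.write("id\tchrom\tpos_1based\ttrait_class\ttrait\n")
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos + 1}\t{s.trait_class}\t{s.trait}\n")


def read_tpm_table(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TPM matrix (TSV, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in sample(s) {bad}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return df


def read_enriched_genes(path: str | Path) -> pd.DataFrame:
    """Read the expression-enriched gene table: gene, cell_type, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "cell_type", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_meme_pwms(path: str | Path) -> list[PWM]:
    """Read position weight matrices in MEME minimal motif format."""
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[tuple[float, float, float, float]] = []

    def flush() -> None:
        nonlocal motif_id, rows
        if motif_id is not None:
            if not rows:
                raise ValueError(f"{path}: motif {motif_id} has no matrix")
            pwms.append(PWM(motif_id, tuple(rows)))
        motif_id, rows = None, []

    with open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                motif_id = line.split()[1]
            elif line.startswith("letter-probability"):
                continue
            elif motif_id is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: motif {motif_id}: bad matrix row")
                rows.append(tuple(vals))  # type: ignore[arg-type]
    flush()
    return pwms


def write_meme_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Region call tables (BED6 + TSV round trip)
# ---------------------------------------------------------------------------

def bed_score(q: float) -> int:
    """BED score for a q-value: ``-100*log10(q)`` rounded, capped at 1000.

    The 100x scale maps q = 0.01 to 200 and saturates at q <= 1e-10, using
    the full 0-1000 BED score range for the q-values the pipeline produces.
    """
    if not 0.0 <= q <= 1.0 or math.isnan(q):
        raise ValueError(f"q-value {q} outside [0,1]")
    if q == 0.0:
        return 1000
    return min(1000, int(round(-100.0 * math.log10(q))))


def write_region_tables(results, tiles, calls, path_prefix: str | Path) -> None:
    """Write the per-region call set as BED6 + a full TSV.

    ``results`` is a sequence of DMR results, ``tiles`` the TileMatrix they
    were computed on, and ``calls`` the per-(region, cell) cLMR calls. The
    TSV carries per-cell mean methylation, the F/p/q statistics and the cLMR
    flags, and round-trips through :func:`read_region_table`.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    region_info = {rid: i for i, rid in enumerate(tiles.regions.index)}
    cells = tiles.cell_types
    cell_means = tiles.cell_mean_rates()
    clmr_by_region: dict[str, set[str]] = {}
    for c in calls:
        if c.is_clmr:
            clmr_by_region.setdefault(c.region_id, set()).add(c.cell_type)

    with open_text(prefix.with_suffix(".bed"), "wt") as bed:
        for res in results:
            row = tiles.regions.loc[res.region_id]
            q = res.q_value
            score = 0 if (q is None or math.isnan(q)) else bed_score(q)
            bed.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{res.region_id}\t{score}\t+\n"
            )

    with open_text(prefix.with_suffix(".tsv"), "wt") as tsv:
        head = ["region_id", "chrom", "start", "end", "f_stat", "df_num", "df_den",
                "p_value", "q_value", "is_cdmr"]
        head += [f"mean_{c}" for c in cells] + [f"clmr_{c}" for c in cells]
        tsv.write("\t".join(head) + "\n")
        for res in results:
            row = tiles.regions.loc[res.region_id]
            i = region_info[res.region_id]
            flags = clmr_by_region.get(res.region_id, set())
            vals = [
                res.region_id, row.chrom, str(row.start), str(row.end),
                repr(res.f_stat), str(res.df_num), str(res.df_den),
                repr(res.p_value), repr(res.q_value), str(int(res.is_cdmr)),
            ]
            vals += [repr(float(cell_means[i, j])) for j in range(len(cells))]
            vals += [str(int(c in flags)) for c in cells]
            tsv.write("\t".join(vals) + "\n")


def read_region_table(path: str | Path) -> pd.DataFrame:
    """Read back the TSV written by :func:`write_region_tables` losslessly."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
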