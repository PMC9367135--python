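# Methods

## Regional methylation and the coverage filter

Tiles are fixed 1 kb windows anchored at coordinate 0 of each chromosome
(the final partial tile is kept if it contains a CpG); a tile with no CpG
in any sample is dropped. Regional methylation is the pooled,
coverage-weighted rate Σn_meth/Σn_total over the tile's CpGs — not the mean
of per-CpG rates — so deeply covered CpGs dominate exactly as they do in
the read data. Strand merging is on by default: plus/minus records of one
CpG dinucleotide are summed at the plus position before tiling, since CpG
methylation is symmetric and the tiles pool both strands anyway.

"Coverage" in the filter means the tile's pooled n_total for a (cell,
animal) sample, with a strict inequality (> 25), and the cell-count rule
(≥ 7 of 9 cell types) must hold in **every** animal. Whether tile coverage
should instead mean mean-per-CpG depth is genuinely ambiguous in regional
WGBS practice; pooled total is the default here because it matches the
pooled-rate definition, and the filter is a parameter
(`FilterSpec(min_coverage, min_cell_types, per_animal)`), not a constant.
Cells that fail the cutoff in a retained tile keep their rate but are
flagged `low_coverage`.

## The cell-effect test

Each retained tile is fitted with `rate ~ cell_type + animal` by ordinary
least squares and the cell effect tested by the extra-sum-of-squares F
against the animal-only reduction, with p from F(df_num, df_den). With two
animals and one library per cell × animal, a random animal intercept is
not separately estimable from its fixed counterpart, so the "mixed model"
of this design *is* the fixed-effects two-way ANOVA; the implementation is
the general least-squares version so that missing cells are handled (the
design matrices are rebuilt from the observed samples and the ranks
recomputed). Degenerate cases are explicit: constant response → F = 0,
p = 1; an exact additive fit (zero residual) → p floored at 1e-300 and
flagged `exact_fit`; no residual degrees of freedom → untestable and
excluded from the FDR batch. Benjamini–Hochberg is applied once across all
testable tiles genome-wide, matching a single reported FDR batch.

The test treats binomial proportions as homoskedastic normals within a
tile. At the default depth (≈300 pooled reads per sample per tile) this is
accurate enough that on null simulations of 2,000 tiles the p-value
distribution is statistically indistinguishable from Uniform(0,1) (the
test suite checks Kolmogorov–Smirnov at α = 0.01); tiles with rates very
near 0 or 1 are the residual source of miscalibration, which is why the
generator keeps baseline rates inside [0.01, 0.99].

## cLMR classification

z-scores are computed across the region's per-**sample** rates (n−1
denominator), then averaged within cell type; the alternative of z-scoring
the nine cell means directly is available via `level="cell"`. The
sample-level default reads "average cell-type z-score" as the average of a
cell's sample z-scores; with balanced samples the two differ only by a
scale factor and give the same ranking. The mean-methylation condition
(< 0.75) is evaluated on the cell mean. A region with zero SD across
samples yields no cLMRs. Both cuts (`z_cut=-1`, `meth_cut=0.75`) are
parameters.

## Annotation conventions

Promoter: 2 kb strictly upstream through the TSS base, strand-aware
(symmetric ±2 kb by flag). TTS window: ±1 kb around the TTS. CGI shore:
2 kb flank of an island. Feature precedence promoter > TTS > exon >
intron > intergenic; any ≥1 bp overlap qualifies. These windows are common
annotation-tool conventions, stated here because several are not uniquely
standard. Each annotated region records both the genes whose span it
overlaps and the genes responsible for its feature class — a promoter tile
wholly upstream of its gene body is paired with that gene, which is what
the integration layer uses. Intergenic regions take the nearest-TSS gene
with distance 0 when the TSS is inside the region and
|closest region base − TSS| + 1 otherwise (ties broken by smaller gene
id); the +1 makes "adjacent" distance 2 — an arbitrary but fixed
convention stated so results are checkable.

Feature enrichment uses tiles (the analysis unit), not base pairs, as
sampling units: upper-tail hypergeometric with universe = retained tiles,
category = tiles of the class, draws = the cell's cLMR tiles, and
score = log2(observed/expected).

## Integration layer

Correlations are Pearson r over per-cell means (nine points): methylation
as the mean of a cell's sample rates, expression as the mean of a cell's
log2(TPM+1) replicates. The log transform stabilizes Pearson on skewed
abundances and can be switched off. Pairs with fewer than three cells or a
constant vector are recorded with undefined r/p and excluded from the
tests. Background sets are equal-size seeded draws (without replacement)
of retained non-cDMR tiles from the same feature stratum, correlated with
their own paired genes. The left-shift comparison is a one-sided rank-sum
test: exact by dynamic programming over doubled midranks (correct under
ties) for pooled n ≤ 50, a tie-corrected continuity-corrected normal
approximation above, and p = 0.5 for the fully tied degenerate case. The
"significantly correlated" threshold for sign classification is nominal
p < 0.05 (configurable); sign enrichment is a one-sided Fisher test of
cDMRs vs background per stratum and sign. Gene-set and GWAS layers are
upper-tail hypergeometric tests; the GWAS universe is all SNPs in the
provided table (the natural choice when the table itself defines the
candidate set), category = SNPs inside any cDMR (half-open interval
membership), draws = the trait class.

## Motif scoring

The average odds score of a sequence is the arithmetic mean over all
windows on both strands of Π_j pwm_j(base)/bg(base), with a uniform
0-order background by default. Window odds are accumulated in sorted
order, which makes score(seq) == score(reverse_complement(seq)) exact in
floating point, a property the tests assert. Windows containing non-ACGT
bases are skipped; a sequence with no scoreable window is dropped with a
counted warning. `average_odds_score` keeps zero PWM entries exact (so
hand-computable toy scores are exact); the enrichment pipeline floors
zeros at 1e-4 before scoring to avoid degenerate all-or-nothing odds on
real-world matrices. Enrichment uses a fixed, deterministic threshold —
the 95th percentile (upper interpolation) of control scores per motif —
and a one-sided Fisher test of positives vs controls above it. This is
deliberately simpler than optimized-threshold enrichment tools: p-values
are method-parallel, not numerically comparable to theirs.

## The synthetic study

The generator emulates the study design end to end with one ground-truth
layout shared by all three outputs. Defaults (chosen once, with the
rationale here, and used as the standing test conditions):

- genome: 2 chromosomes × 1 Mb → 2,000 tiles; desk-scale but large enough
  for calibration tests;
- CpG spacing ~Exp(100 bp) between CpGs, ten-fold denser inside CpG
  islands, giving islands an observed/expected CpG ratio well above 0.6
  and the open genome well below it;
- baseline tile methylation ~Beta(8, 2) clipped to [0.01, 0.99]: mean 0.8,
  matching the 80–84% global CpG methylation typical of sorted immune
  cells, with mass at high rates as in real methylomes;
- per-CpG depth ~Poisson(30), a typical WGBS coverage; methylated counts
  are Binomial(depth, rate);
- animal effect: one N(0, 0.1) offset per animal added on the logit scale,
  keeping rates in (0,1) while honoring the additive animal term;
- planted cDMRs: 80 tiles (default) whose baseline leaves room for the
  effect; the target cell's rate is reduced by `dmr_effect` (0.3);
- expression: linked genes' log2 abundance is a linear function of the
  linked tile's true per-cell methylation (slope 8 log2 units per unit
  methylation, sign −1) plus N(0, 0.25) replicate noise on the log scale;
  unlinked genes have flat cell means. 30% of genes are linked by default,
  their linked tile being the tile immediately upstream of their TSS;
- SNPs: 25% "immune capacity", 60% of those placed uniformly inside
  planted cDMR tiles; the rest uniform over the genome;
- motifs: one planted width-8 PWM (consensus probability 0.85) embedded in
  60% of planted-tile sequences, plus 10 random decoy PWMs; sequences are
  uniform ACGT.

What the generator does **not** emulate: read-level data (FASTQ),
bisulfite conversion errors, non-CpG contexts, overdispersed coverage,
spatial correlation of methylation along the genome, multi-isoform genes,
and sequence-dependent CpG placement (CpG density is simulated directly,
the FASTA sequences are background plus planted consensus only). Passing
tests therefore demonstrate correctness of the statistical machinery and
end-to-end signal propagation under the stated model, not robustness to
every property of real WGBS data.

Determinism: each stage draws from an independent child generator of the
config seed (`default_rng([seed, stage])`), so a fixed seed reproduces all
outputs byte-identically and the three generator entry points can be
called in any order.

## Problem sizes used in checks

The package's standing checks run at: 2,000 tiles for null calibration
(no planted effect; KS uniformity and ≤ 2 false discoveries at q < 0.01);
3 × 5,000 tiles with 200 planted events at effect 0.3 for recovery
(sensitivity ≥ 0.9, empirical FDR ≤ 0.05, ≥ 95% of detected planted
events cLMR-classified in the correct cell); the default 2,000-tile study
for integration, motif and GWAS recovery. These sizes were chosen as the
smallest at which the binomial and rank statistics are comfortably in
their asymptotic regimes; the acceptance script uses the same defaults.

## Known limitations

- The F test's normal approximation degrades for tiles with very few CpGs
  at extreme rates; such tiles are retained (the filter is on coverage,
  not CpG count), so a handful of marginal planted events can be missed at
  effect sizes near the noise floor.
- One library per cell × animal means animal-by-cell interaction is not
  estimable and is absorbed into the residual.
- The motif layer scores fixed-length tile sequences; it does not model
  positional preference within the tile.
- `summarize_clmr_uniqueness` percentages are rounded to one decimal, the
  precision at which such tables are conventionally reported.
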