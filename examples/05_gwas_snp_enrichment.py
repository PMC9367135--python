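"""Test whether trait-associated SNPs concentrate inside cDMRs.

Universe = every SNP in the table; category = SNPs falling in any cDMR;
draws = the SNPs of one trait class; the p-value is the upper-tail
hypergeometric probability of at least the observed overlap.
"""

from tilemeth import (
    SimConfig,
    apply_coverage_filter,
    call_cdmrs,
    gwas_snp_enrichment,
    simulate_annotation_and_snps,
    simulate_methylomes,
    tile_counts,
)

config = SimConfig(seed=0)
reports, truth = simulate_methylomes(config)
ann = simulate_annotation_and_snps(config, truth)
retained = apply_coverage_filter(
    tile_counts(reports, config.sample_sheet(), chrom_lengths=config.chrom_lengths)
)
called = {r.region_id for r in call_cdmrs(retained) if r.is_cdmr}
cdmr_regions = [
    (r.chrom, int(r.start), int(r.end))
    for rid, r in retained.regions.iterrows()
    if rid in called
]

print(f"{len(ann.snps)} SNPs, {len(cdmr_regions)} cDMRs "
      f"({len(truth.planted_snps_in_dmrs)} immune-capacity SNPs planted inside cDMRs)")
for trait_class, e in gwas_snp_enrichment(ann.snps, cdmr_regions).items():
    print(f"  {trait_class:<16} in cDMRs: {e.observed:>3} of {e.draw_n} "
          f"(expected {e.expected:4.1f})  p={e.p:.3g}")
print("\nA small p for one class and p~1 for the rest means cDMRs capture")
print("trait-associated variation specifically, not SNP density in general.")
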