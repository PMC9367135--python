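import math

import numpy as np
import pandas as pd
import pytest

from tilemeth.annotate import FeatureAnnotation
from tilemeth.integrate import (
    background_correlation_test,
    clmr_gene_set_enrichment,
    correlate_regions,
    gwas_snp_enrichment,
    sign_enrichment_test,
    snps_in_regions,
    CorrelationResult,
)
from tilemeth.io import SNPRecord, SampleMeta
from tilemeth.tiling import TileMatrix


def _tiles_one_region(rates_by_cell):
    cells = list(rates_by_cell)
    samples = [SampleMeta(f"{c}_a1", c, "a1") for c in cells]
    denom = 1000
    meth = np.array([[int(round(rates_by_cell[c] * denom)) for c in cells]])
    totals = np.full((1, len(cells)), denom)
    regions = pd.DataFrame(
        [("chr1:0-1000", "chr1", 0, 1000, 5)],
        columns=["region_id", "chrom", "start", "end", "n_cpg"],
    ).set_index("region_id")
    return TileMatrix(regions, samples, meth, totals), samples


class TestCorrelateRegions:
    def test_perfect_anticorrelation(self):
        tiles, samples = _tiles_one_region({"c1": 0.1, "c2": 0.5, "c3": 0.9})
        ann = [FeatureAnnotation("chr1:0-1000", "promoter", "non_cgi", (), ("gX",))]
        tpm = pd.DataFrame({"c1_a1": [9.0], "c2_a1": [5.0], "c3_a1": [1.0]}, index=["gX"])
        out = correlate_regions(
            ["chr1:0-1000"], ann, tiles, tpm,
            {s.sample_id: s.cell_type for s in samples}, log_transform=False,
        )
        assert len(out) == 1
        assert out[0].r == pytest.approx(-1.0, abs=1e-12)
        assert out[0].stratum == "promoter"

    def test_constant_tpm_undefined_and_excluded(self):
        tiles, samples = _tiles_one_region({"c1": 0.1, "c2": 0.5, "c3": 0.9})
        ann = [FeatureAnnotation("chr1:0-1000", "promoter", "non_cgi", (), ("gX",))]
        tpm = pd.DataFrame({"c1_a1": [2.0], "c2_a1": [2.0], "c3_a1": [2.0]}, index=["gX"])
        out = correlate_regions(
            ["chr1:0-1000"], ann, tiles, tpm,
            {s.sample_id: s.cell_type for s in samples},
        )
        assert math.isnan(out[0].r) and math.isnan(out[0].p)

    def test_pearson_matches_closed_form_on_three_points(self, rng):
        for _ in range(5):
            m = rng.uniform(size=3)
            e = rng.uniform(size=3)
            if np.ptp(m) == 0 or np.ptp(e) == 0:
                continue
            tiles, samples = _tiles_one_region(
                {f"c{i}": m[i] for i in range(3)}
            )
            ann = [FeatureAnnotation("chr1:0-1000", "promoter", "non_cgi", (), ("gX",))]
            tpm = pd.DataFrame(
                {f"c{i}_a1": [e[i]] for i in range(3)}, index=["gX"]
            )
            out = correlate_regions(
                ["chr1:0-1000"], ann, tiles, tpm,
                {s.sample_id: s.cell_type for s in samples}, log_transform=False,
            )
            mm = tiles.rates[0]
            closed = ((mm - mm.mean()) * (e - e.mean())).sum() / math.sqrt(
                ((mm - mm.mean()) ** 2).sum() * ((e - e.mean()) ** 2).sum()
            )
            assert out[0].r == pytest.approx(closed, abs=1e-12)

    def test_planted_links_recovered(self, study):
        linked = {rid for _, rid, _ in study.truth.gene_region_links}
        corrs = correlate_regions(
            sorted(linked), study.annotations, study.retained, study.tpm,
            study.cell_of_sample,
        )
        link_set = {(g, r) for g, r, _ in study.truth.gene_region_links}
        rs = [c.r for c in corrs if (c.gene_id, c.region_id) in link_set]
        assert len(rs) == len(linked)
        frac_strong = np.mean([r < -0.7 for r in rs])
        assert frac_strong >= 0.9


class TestBackgroundComparison:
    def test_background_draw_seeded_and_disjoint(self, study):
        corrs = correlate_regions(
            [r.region_id for r in study.cdmrs], study.annotations,
            study.retained, study.tpm, study.cell_of_sample,
        )
        kwargs = dict(
            cdmr_ids=[r.region_id for r in study.cdmrs],
            annotations=study.annotations,
            tiles=study.retained,
            tpm=study.tpm,
            cell_of_sample=study.cell_of_sample,
        )
        a = background_correlation_test(corrs, seed=42, **kwargs)
        b = background_correlation_test(corrs, seed=42, **kwargs)
        c = background_correlation_test(corrs, seed=43, **kwargs)
        assert {s: x.background_regions for s, x in a.items()} == {
            s: x.background_regions for s, x in b.items()
        }
        assert any(
            a[s].background_regions != c[s].background_regions for s in a
        )
        cdmr_set = {r.region_id for r in study.cdmrs}
        for comp in a.values():
            assert not (set(comp.background_regions) & cdmr_set)

    def test_left_shift_detected_for_promoter_stratum(self, study):
        corrs = correlate_regions(
            [r.region_id for r in study.cdmrs], study.annotations,
            study.retained, study.tpm, study.cell_of_sample,
        )
        comps = background_correlation_test(
            corrs, [r.region_id for r in study.cdmrs], study.annotations,
            study.retained, study.tpm, study.cell_of_sample, seed=11,
        )
        assert comps["promoter"].rank_sum.p < 0.01


def _corr(stratum, r, p, i):
    return CorrelationResult(f"r{i}", f"g{i}", stratum, r, p, 9)


class TestSignEnrichment:
    def test_diagonal_table_example(self):
        fg = [_corr("promoter", -0.9, 0.001, i) for i in range(2)]
        bg = [_corr("promoter", 0.1, 0.8, 10 + i) for i in range(2)]
        out = {
            (s.stratum, s.sign): s for s in sign_enrichment_test(fg, bg)
        }
        neg = out[("promoter", "negative")]
        assert neg.table == ((2, 0), (0, 2))
        assert neg.p == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_proportions_not_significant(self):
        fg = [_corr("tts", -0.9, 0.01, i) for i in range(2)] + [
            _corr("tts", 0.1, 0.9, 2)
        ]
        bg = [_corr("tts", -0.8, 0.02, 10 + i) for i in range(2)] + [
            _corr("tts", 0.2, 0.9, 13)
        ]
        out = {(s.stratum, s.sign): s for s in sign_enrichment_test(fg, bg)}
        assert out[("tts", "negative")].p >= 0.5

    def test_no_significant_regions_gives_p_one(self):
        fg = [_corr("intergenic", 0.1, 0.9, 1)]
        bg = [_corr("intergenic", -0.1, 0.8, 2)]
        for s in sign_enrichment_test(fg, bg):
            assert s.p == 1.0


class TestGeneSetEnrichment:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(20)}
        clmr = {"NK": {f"g{i}" for i in range(4)}}
        enriched = {"NK": {f"g{i}" for i in range(5)}}
        df = clmr_gene_set_enrichment(clmr, enriched, universe)
        assert df.iloc[0]["p"] == pytest.approx(5 / 4845, abs=1e-12)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        df = clmr_gene_set_enrichment(
            {"NK": {"g0", "g1"}}, {"CD4T": {"g8", "g9"}}, universe
        )
        assert (df["p"] >= (1 - 1e-12)).all() or df.iloc[0]["observed"] == 0

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            clmr_gene_set_enrichment({"NK": {"gX"}}, {}, {"g0"})

    def test_planted_links_enrich_matching_cell(self, study):
        from tilemeth.annotate import region_gene_map

        gene_map = region_gene_map(study.annotations)
        universe = set(study.tpm.index)
        clmr_genes = {
            cell: {
                g
                for c in study.calls
                if c.is_clmr and c.cell_type == cell
                for g in gene_map.get(c.region_id, ())
            }
            & universe
            for cell in study.retained.cell_types
        }
        enriched_sets = {
            cell: set(sub["gene"]) & universe
            for cell, sub in study.enriched.groupby("cell_type")
        }
        df = clmr_gene_set_enrichment(clmr_genes, enriched_sets, universe)
        same = df[df.clmr_cell == df.enriched_cell]["p"]
        diff = df[df.clmr_cell != df.enriched_cell]["p"]
        assert same.min() < diff.min()


class TestGwasEnrichment:
    def test_all_class_snps_in_cdmrs_minimal_tail(self):
        cdmrs = [("chr1", 0, 1000)]
        snps = [SNPRecord(f"i{k}", "chr1", 10 + k, "immune") for k in range(3)]
        snps += [SNPRecord(f"o{k}", "chr1", 5000 + k, "other") for k in range(5)]
        out = gwas_snp_enrichment(snps, cdmrs)
        # universe 8, category (in cDMR) 3, draws 3, observed 3 -> 1/C(8,3)
        assert out["immune"].p == pytest.approx(1 / 56, abs=1e-12)

    def test_half_open_interval_membership(self):
        cdmrs = [("chr1", 100, 200)]
        snps = [
            SNPRecord("a", "chr1", 100, "t"),
            SNPRecord("b", "chr1", 199, "t"),
            SNPRecord("c", "chr1", 200, "t"),
        ]
        assert snps_in_regions(snps, cdmrs) == {"a", "b"}

    def test_unknown_chromosome_excluded_with_warning(self):
        snps = [
            SNPRecord("a", "chr1", 5, "t"),
            SNPRecord("b", "chrUn", 5, "t"),
        ]
        with pytest.warns(UserWarning, match="unknown"):
            out = gwas_snp_enrichment(snps, [("chr1", 0, 10)], known_chroms={"chr1"})
        assert out["t"].universe_n == 1

    def test_null_placement_is_uniform(self, rng):
        # SNPs placed uniformly: enrichment p should not be systematically small
        cdmrs = [("chr1", i * 10_000, i * 10_000 + 1000) for i in range(10)]
        ps = []
        for _ in range(40):
            snps = [
                SNPRecord(f"s{k}", "chr1", int(p), "classA" if k < 30 else "classB")
                for k, p in enumerate(rng.integers(0, 100_000, size=60))
            ]
            ps.append(gwas_snp_enrichment(snps, cdmrs)["classA"].p)
        assert np.mean(ps) > 0.2

    def test_planted_snps_detected(self, study):
        cdmr_ids = {r.region_id for r in study.cdmrs}
        cdmr_regions = [
            (row.chrom, int(row.start), int(row.end))
            for rid, row in study.retained.regions.iterrows()
            if rid in cdmr_ids
        ]
        out = gwas_snp_enrichment(study.ann.snps, cdmr_regions)
        assert out["immune capacity"].p < 1e-6
        assert out["other"].p > 0.05
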