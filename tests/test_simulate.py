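import hashlib

import numpy as np
import pytest

from tilemeth.simulate import (
    SimConfig,
    simulate_annotation_and_snps,
    simulate_expression,
    simulate_methylomes,
    write_simulation,
)
from tilemeth.tiling import region_id

SMALL = dict(
    n_chroms=1,
    chrom_length_bp=200_000,
    n_genes=10,
    n_cgis=6,
    n_dmr_planted=8,
    n_snps=40,
    seed=7,
)


def small_config(**overrides):
    return SimConfig(**{**SMALL, **overrides})


def checksum(reports):
    h = hashlib.sha256()
    for sid in sorted(reports):
        for rec in reports[sid]:
            h.update(repr(rec).encode())
    return h.hexdigest()


class TestSimulateMethylomes:
    def test_one_report_per_cell_animal(self):
        cfg = small_config()
        reports, _ = simulate_methylomes(cfg)
        assert set(reports) == {
            f"{c}_{a}" for c in cfg.cell_types for a in cfg.animals
        }

    def test_null_config_has_equal_expected_rates(self):
        cfg = small_config(n_dmr_planted=0, animal_effect_sd=0.0,
                           frac_genes_correlated=0.0)
        _, truth = simulate_methylomes(cfg)
        assert (truth.true_rates == truth.true_rates[:, [0]]).all()
        assert all(v == 0.0 for v in truth.animal_offsets.values())

    def test_planted_effect_construction(self):
        cfg = small_config(dmr_effect=0.5)
        _, truth = simulate_methylomes(cfg)
        ix = truth.tile_index()
        for p in truth.planted_dmrs:
            i = ix[p.region_id]
            j = truth.cell_types.index(p.target_cell)
            assert truth.true_rates[i, j] == pytest.approx(p.baseline_rate - 0.5)
            others = np.delete(truth.true_rates[i], j)
            assert others == pytest.approx(p.baseline_rate)

    def test_determinism_same_seed_same_checksum(self):
        a, _ = simulate_methylomes(small_config())
        b, _ = simulate_methylomes(small_config())
        c, _ = simulate_methylomes(small_config(seed=8))
        assert checksum(a) == checksum(b)
        assert checksum(a) != checksum(c)

    def test_count_consistency_depth_equals_meth_plus_unmeth(self):
        reports, _ = simulate_methylomes(small_config())
        rec = reports["NK_A1"][0]
        assert rec.n_total == rec.n_meth + rec.n_unmeth
        assert all(r.n_meth >= 0 and r.n_unmeth >= 0 for r in reports["NK_A1"][:100])

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError, match="n_animals"):
            simulate_methylomes(small_config(n_animals=1))

    def test_bad_effect_rejected(self):
        with pytest.raises(ValueError, match="dmr_effect"):
            simulate_methylomes(small_config(dmr_effect=1.5))

    def test_planted_signal_fidelity(self):
        """Empirical rate gap at planted tiles within 3 binomial SEs of the
        planted effect."""
        cfg = small_config(animal_effect_sd=0.0)
        reports, truth = simulate_methylomes(cfg)
        from tilemeth.tiling import tile_counts

        tiles = tile_counts(reports, cfg.sample_sheet())
        ix = {rid: i for i, rid in enumerate(tiles.regions.index)}
        rates = tiles.rates
        cells = tiles.cell_types
        for p in truth.planted_dmrs:
            i = ix[p.region_id]
            j = cells.index(p.target_cell)
            cols_t = [k for k, s in enumerate(tiles.samples) if s.cell_type == p.target_cell]
            cols_o = [k for k, s in enumerate(tiles.samples) if s.cell_type != p.target_cell]
            gap = np.nanmean(rates[i, cols_o]) - np.nanmean(rates[i, cols_t])
            n_t = tiles.n_total[i, cols_t].sum()
            se = np.sqrt(p.baseline_rate * (1 - p.baseline_rate) / max(n_t, 1)) * 2
            assert gap == pytest.approx(p.effect, abs=max(3 * se, 0.05))

    def test_cgi_cpg_density_contrast(self):
        """Observed/expected CpG ratio (uniform base model) exceeds 0.6 in
        CGIs and stays below it outside."""
        cfg = small_config()
        reports, truth = simulate_methylomes(cfg)
        positions = np.array(sorted({r.pos for r in reports["NK_A1"]}))
        in_cgi = np.zeros(positions.size, dtype=bool)
        cgi_bp = 0
        for chrom, s, e in truth.cgi_intervals:
            in_cgi |= (positions >= s) & (positions < e)
            cgi_bp += e - s
        genome_bp = cfg.chrom_length_bp * cfg.n_chroms
        oe_cgi = in_cgi.sum() / (cgi_bp / 16)
        oe_out = (~in_cgi).sum() / ((genome_bp - cgi_bp) / 16)
        assert oe_cgi > 0.6
        assert oe_out < 0.6


class TestSimulateExpression:
    def test_noise_free_monotone_reversal(self):
        cfg = small_config(expression_noise_sd=0.0)
        _, truth = simulate_methylomes(cfg)
        tpm, _ = simulate_expression(cfg, truth)
        ix = truth.tile_index()
        cells = list(truth.cell_types)
        for gene_id, rid, sign in truth.gene_region_links:
            assert sign == -1
            m = truth.true_rates[ix[rid]]
            expr = tpm.loc[gene_id, [f"{c}_A1" for c in cells]].to_numpy()
            assert (np.argsort(np.argsort(expr)) == np.argsort(np.argsort(-m))).all()

    def test_unlinked_genes_uncorrelated_on_average(self):
        """Monte-Carlo under independence: over 200 (unlinked gene, random
        tile) pairs, the mean Pearson r of cell-mean expression vs observed
        cell-mean methylation is within 0.1 of zero."""
        cfg = SimConfig(n_chroms=1, chrom_length_bp=1_000_000, n_genes=50,
                        frac_genes_correlated=0.0, n_dmr_planted=0, seed=9)
        reports, truth = simulate_methylomes(cfg)
        tpm, _ = simulate_expression(cfg, truth)
        from tilemeth.tiling import tile_counts

        tiles = tile_counts(reports, cfg.sample_sheet())
        meth = tiles.cell_mean_rates()
        cells = tiles.cell_types
        log_tpm = np.log2(tpm + 1.0)
        expr = {
            g: np.array([
                log_tpm.loc[g, [f"{c}_{a}" for a in cfg.animals]].mean()
                for c in cells
            ])
            for g in tpm.index
        }
        rng = np.random.default_rng(4)
        genes = list(tpm.index)
        rs = []
        for k in range(200):
            e = expr[genes[k % len(genes)]]
            m = meth[int(rng.integers(meth.shape[0]))]
            if np.ptp(e) == 0 or np.ptp(m) == 0 or np.isnan(m).any():
                continue
            rs.append(np.corrcoef(m, e)[0, 1])
        assert len(rs) > 150
        assert abs(np.mean(rs)) < 0.1

    def test_enriched_table_deterministic_and_valid(self):
        cfg = small_config()
        _, truth = simulate_methylomes(cfg)
        _, enr_a = simulate_expression(cfg, truth)
        _, enr_b = simulate_expression(cfg, truth)
        assert enr_a.equals(enr_b)
        assert (enr_a["log2fc"] > 1).all()
        assert (enr_a["fdr"] < 0.05).all()

    def test_unknown_gene_link_rejected(self):
        cfg = small_config()
        _, truth = simulate_methylomes(cfg)
        truth.gene_region_links.append(("NOT_A_GENE", truth.planted_dmrs[0].region_id, -1))
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_expression(cfg, truth)


class TestSimulateAnnotationAndSnps:
    def test_gene_models_valid_and_nonoverlapping(self):
        cfg = small_config()
        _, truth = simulate_methylomes(cfg)
        ann = simulate_annotation_and_snps(cfg, truth)
        assert len(ann.genes) == cfg.n_genes
        by_chrom = {}
        for g in ann.genes:
            assert g.start < g.end
            if g.strand == "+":
                assert g.tss < g.tts
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_planted_snp_fraction_one_all_inside_cdmrs(self):
        cfg = small_config(snp_in_cdmr_frac=1.0, immune_snp_frac=0.3)
        _, truth = simulate_methylomes(cfg)
        ann = simulate_annotation_and_snps(cfg, truth)
        planted = {(p.chrom, p.start, p.end) for p in truth.planted_dmrs}
        immune = [s for s in ann.snps if s.trait_class == "immune capacity"]
        assert immune
        for s in immune:
            assert any(c == s.chrom and a <= s.pos < b for c, a, b in planted)

    def test_consensus_embedded_in_every_carrier(self):
        cfg = small_config(motif_carrier_rate=1.0)
        _, truth = simulate_methylomes(cfg)
        ann = simulate_annotation_and_snps(cfg, truth)
        planted_pwm = next(p for p in ann.pwms if p.motif_id == truth.planted_motif_id)
        consensus = planted_pwm.consensus
        assert truth.motif_carrier_ids
        for rid in truth.motif_carrier_ids:
            assert consensus in ann.positive_seqs[rid]

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_methylomes(small_config(n_genes=40))


def test_written_files_reproducible(tmp_path):
    cfg = small_config()

    def run(sub):
        reports, truth = simulate_methylomes(cfg)
        tpm, enriched = simulate_expression(cfg, truth)
        ann = simulate_annotation_and_snps(cfg, truth)
        out = tmp_path / sub
        write_simulation(cfg, out, reports, truth, tpm, enriched, ann)
        return {
            p.name: hashlib_digest(p) for p in sorted(out.iterdir())
        }

    def hashlib_digest(p):
        return hashlib.sha256(p.read_bytes()).hexdigest()

    assert run("a") == run("b")
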