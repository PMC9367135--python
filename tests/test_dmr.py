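import math

import numpy as np
import pytest

from tilemeth.dmr import (
    CLMRCall,
    bh_fdr,
    call_cdmrs,
    cell_effect_anova,
    classify_clmrs,
    summarize_clmr_uniqueness,
)
from tilemeth.io import SampleMeta


def balanced_anova_oracle(rates, n_cells, n_animals):
    """Classical two-way ANOVA cell-effect F from the direct sum-of-squares
    formulas, valid for complete balanced designs (one obs per cell x animal).

    ``rates`` is an (n_cells, n_animals) array.
    """
    y = np.asarray(rates, dtype=float)
    grand = y.mean()
    ss_cell = n_animals * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_animal = n_cells * ((y.mean(axis=0) - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ss_cell - ss_animal
    df_num = n_cells - 1
    df_den = (n_cells - 1) * (n_animals - 1)
    return (ss_cell / df_num) / (sse / df_den), df_num, df_den


class TestCellEffectAnova:
    def test_hand_worked_three_by_two_design(self, balanced_samples):
        rates = [0.1, 0.2, 0.3, 0.4, 0.8, 0.7]
        res = cell_effect_anova(rates, balanced_samples)
        assert res.f_stat == pytest.approx(28.0, abs=1e-9)
        assert (res.df_num, res.df_den) == (2, 2)
        assert res.p_value == pytest.approx(1 / 29, abs=1e-6)

    def test_constant_response_gives_f_zero_p_one(self, balanced_samples):
        res = cell_effect_anova([0.5] * 6, balanced_samples)
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_exact_additive_fit_flagged_with_floored_p(self, balanced_samples):
        # rates = cell effect + animal effect exactly (zero residual)
        cell = {"c1": 0.1, "c2": 0.3, "c3": 0.6}
        animal = {"a1": 0.0, "a2": 0.05}
        rates = [cell[s.cell_type] + animal[s.animal] for s in balanced_samples]
        res = cell_effect_anova(rates, balanced_samples)
        assert res.exact_fit
        assert res.p_value <= 1e-300

    def test_missing_cells_allowed(self, balanced_samples):
        rates = [0.1, 0.2, np.nan, np.nan, 0.8, 0.7]  # c2 fully missing
        res = cell_effect_anova(rates, balanced_samples)
        assert res.testable
        assert res.df_num == 1

    def test_single_animal_untestable(self):
        samples = [SampleMeta(f"c{i}_a1", f"c{i}", "a1") for i in range(3)]
        res = cell_effect_anova([0.1, 0.5, 0.9], samples)
        assert not res.testable and math.isnan(res.p_value)

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_balanced_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cells, n_animals = 9, 2
        samples = [
            SampleMeta(f"c{i}_a{j}", f"c{i}", f"a{j}")
            for i in range(n_cells)
            for j in range(n_animals)
        ]
        y = rng.uniform(0.1, 0.9, size=(n_cells, n_animals))
        res = cell_effect_anova(y.ravel(), samples)
        f_oracle, df_num, df_den = balanced_anova_oracle(y, n_cells, n_animals)
        assert res.f_stat == pytest.approx(f_oracle, abs=1e-8)
        assert (res.df_num, res.df_den) == (df_num, df_den)


class TestBHFDR:
    def test_step_up_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_monotone_after_adjustment(self, rng):
        p = np.sort(rng.uniform(size=40))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        assert q[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallCdmrs:
    def test_threshold_one_calls_every_testable_tile(self, study):
        res = call_cdmrs(study.retained, fdr_threshold=1.0000001)
        assert all(r.is_cdmr for r in res if r.testable)

    def test_planted_effect_is_called(self, study):
        called = {r.region_id for r in study.results if r.is_cdmr}
        planted = study.truth.planted_region_ids()
        assert len(called & planted) / len(planted) >= 0.9

    def test_empty_matrix_gives_empty_list(self, study):
        empty = study.retained.subset(np.array([], dtype=int))
        assert call_cdmrs(empty) == []


def _single_sample_tiles(rates_by_cell):
    """One region, one sample per cell type, with given pooled rates."""
    import pandas as pd
    from tilemeth.tiling import TileMatrix

    cells = list(rates_by_cell)
    samples = [SampleMeta(f"{c}_a1", c, "a1") for c in cells]
    denom = 1000
    totals = np.full((1, len(cells)), denom)
    meth = np.array([[int(round(rates_by_cell[c] * denom)) for c in cells]])
    regions = pd.DataFrame(
        [("chr1:0-1000", "chr1", 0, 1000, 5)],
        columns=["region_id", "chrom", "start", "end", "n_cpg"],
    ).set_index("region_id")
    return TileMatrix(regions, samples, meth, totals)


def _cdmr_result(region_id="chr1:0-1000"):
    from tilemeth.dmr import DMRResult

    return [DMRResult(region_id, 10.0, 8, 8, 1e-6, 1e-5, is_cdmr=True)]


class TestClassifyClmrs:
    def test_hand_worked_z_score(self):
        rates = {f"c{i}": 0.9 for i in range(8)}
        rates["low"] = 0.1
        tiles = _single_sample_tiles(rates)
        calls = classify_clmrs(_cdmr_result(), tiles)
        low = next(c for c in calls if c.cell_type == "low")
        assert low.avg_z == pytest.approx(-2.6667, abs=1e-3)
        assert low.mean_rate == pytest.approx(0.1)
        assert low.is_clmr

    def test_meth_cut_binds_even_when_z_low(self):
        rates = {f"c{i}": 0.95 for i in range(8)}
        rates["low"] = 0.80
        tiles = _single_sample_tiles(rates)
        calls = classify_clmrs(_cdmr_result(), tiles)
        low = next(c for c in calls if c.cell_type == "low")
        assert low.avg_z < -1
        assert not low.is_clmr  # mean rate 0.80 > 0.75

    def test_z_scores_sum_to_zero(self):
        rates = {f"c{i}": r for i, r in enumerate([0.2, 0.4, 0.5, 0.6, 0.8])}
        tiles = _single_sample_tiles(rates)
        calls = classify_clmrs(_cdmr_result(), tiles)
        assert sum(c.avg_z for c in calls) == pytest.approx(0.0, abs=1e-12)

    def test_constant_region_yields_no_clmrs(self):
        tiles = _single_sample_tiles({f"c{i}": 0.5 for i in range(9)})
        calls = classify_clmrs(_cdmr_result(), tiles)
        assert not any(c.is_clmr for c in calls)

    def test_invariant_to_sample_order_and_animal_labels(self, study):
        tiles = study.retained
        perm = np.random.default_rng(0).permutation(len(tiles.samples))
        from tilemeth.tiling import TileMatrix

        relabel = {"A1": "zebra", "A2": "aardvark"}
        shuffled = TileMatrix(
            tiles.regions,
            [
                SampleMeta(
                    tiles.samples[i].sample_id,
                    tiles.samples[i].cell_type,
                    relabel[tiles.samples[i].animal],
                )
                for i in perm
            ],
            tiles.n_meth[:, perm],
            tiles.n_total[:, perm],
        )
        a = {
            (c.region_id, c.cell_type): c.is_clmr
            for c in classify_clmrs(study.results, tiles)
        }
        b = {
            (c.region_id, c.cell_type): c.is_clmr
            for c in classify_clmrs(study.results, shuffled)
        }
        assert a == b


class TestSummarizeUniqueness:
    def _calls(self, cell, total, unique, other="OTHER"):
        calls = []
        for i in range(total):
            calls.append(CLMRCall(f"{cell}:r{i}", cell, 0.1, -2.0, True))
            if i >= unique:
                calls.append(CLMRCall(f"{cell}:r{i}", other, 0.1, -2.0, True))
        return calls

    def test_single_cell_is_fully_unique(self):
        df = summarize_clmr_uniqueness(self._calls("NK", 10, 10))
        assert df.loc["NK", "pct_unique"] == 100.0

    def test_region_and_gene_percentages(self):
        calls = self._calls("CD4T", 20, 5)
        gene_map = {f"CD4T:r{i}": (f"g{i}",) for i in range(8)}
        df = summarize_clmr_uniqueness(calls, gene_map)
        assert df.loc["CD4T", "n_clmrs"] == 20
        assert df.loc["CD4T", "pct_unique"] == 25.0
        # genes on shared regions (r5..r7) are shared with OTHER
        assert df.loc["CD4T", "n_genes"] == 8
        assert df.loc["CD4T", "n_unique_genes"] == 5
        assert df.loc["CD4T", "pct_unique_genes"] == 62.5
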