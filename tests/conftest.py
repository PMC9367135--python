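import numpy as np
import pytest

from tilemeth import (
    SimConfig,
    apply_coverage_filter,
    call_cdmrs,
    classify_clmrs,
    simulate_annotation_and_snps,
    simulate_expression,
    simulate_methylomes,
    tile_counts,
)
from tilemeth.annotate import annotate_regions
from tilemeth.io import SampleMeta


class Study:
    """A fully simulated and processed study, shared across tests."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.reports, self.truth = simulate_methylomes(config)
        self.tpm, self.enriched = simulate_expression(config, self.truth)
        self.ann = simulate_annotation_and_snps(config, self.truth)
        self.samples = config.sample_sheet()
        self.tiles = tile_counts(
            self.reports, self.samples, chrom_lengths=config.chrom_lengths
        )
        self.retained = apply_coverage_filter(self.tiles)
        self.results = call_cdmrs(self.retained)
        self.cdmrs = [r for r in self.results if r.is_cdmr]
        self.calls = classify_clmrs(self.results, self.retained)
        self.annotations = annotate_regions(
            [
                (rid, row.chrom, int(row.start), int(row.end))
                for rid, row in self.retained.regions.iterrows()
            ],
            self.ann.genes,
            self.ann.cgis,
        )
        self.cell_of_sample = {s.sample_id: s.cell_type for s in self.samples}


@pytest.fixture(scope="session")
def study() -> Study:
    """Default synthetic study: 2,000 tiles, 80 planted cDMRs, 18 linked genes."""
    return Study(SimConfig(seed=3))


@pytest.fixture
def balanced_samples() -> list[SampleMeta]:
    """Three cell types x two animals, the smallest balanced design."""
    return [
        SampleMeta(f"{c}_{a}", c, a)
        for c in ("c1", "c2", "c3")
        for a in ("a1", "a2")
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
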