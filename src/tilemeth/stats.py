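"""Shared enrichment and rank statistics.

Hypergeometric and Fisher tests go through scipy; the rank-sum test is
implemented here because the pipeline needs an exact small-sample p-value
that is correct under ties (a dynamic program over doubled midranks), with a
tie-corrected, continuity-corrected normal approximation for large samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class EnrichmentResult:
    """An overlap enrichment test: observed vs expected under sampling
    without replacement from a finite universe, with the upper-tail
    hypergeometric p-value."""

    observed: int
    expected: float
    score: float  # log2(observed/expected); nan when undefined
    p: float
    universe_n: int
    category_n: int
    draw_n: int


def hypergeom_enrichment(
    observed: int, universe_n: int, category_n: int, draw_n: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= observed).

    ``universe_n`` objects, ``category_n`` of them in the category,
    ``draw_n`` drawn; ``observed`` drawn objects found in the category.
    """
    if not 0 <= category_n <= universe_n:
        raise ValueError("category_n outside [0, universe_n]")
    if not 0 <= draw_n <= universe_n:
        raise ValueError("draw_n outside [0, universe_n]")
    if observed > min(category_n, draw_n):
        raise ValueError("observed exceeds min(category_n, draw_n)")
    p = float(sps.hypergeom.sf(observed - 1, universe_n, category_n, draw_n))
    p = min(1.0, max(0.0, p))
    expected = draw_n * category_n / universe_n if universe_n else float("nan")
    if expected > 0:
        score = math.log2(observed / expected) if observed > 0 else -math.inf
    else:
        score = float("nan")
    return EnrichmentResult(observed, expected, score, p, universe_n, category_n, draw_n)


def fisher_greater(table) -> tuple[float, float]:
    """One-sided Fisher's exact test (alternative: first row enriched in
    first column). Returns (odds_ratio, p)."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("Fisher table must be 2x2 non-negative")
    odds, p = sps.fisher_exact(tab, alternative="greater")
    return float(odds), float(p)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample (midranks)
    p: float
    n_x: int
    n_y: int
    method: str  # "exact", "normal", or "degenerate"


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_ranksum_cdf(ranks2: np.ndarray, n_x: int, r2_obs: int) -> float:
    """P(R_x <= r_obs) for the rank sum of a random n_x-subset of the pooled
    midranks, computed exactly by dynamic programming.

    ``ranks2`` are the pooled midranks doubled (integers even under ties);
    ``r2_obs`` the doubled observed rank sum.
    """
    total = int(ranks2.sum())
    # counts[k][s] = number of k-subsets with doubled rank sum s
    counts = np.zeros((n_x + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n_x, 1_000_000), 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    n_total = counts[n_x].sum()
    tail = counts[n_x, : r2_obs + 1].sum()
    return float(tail / n_total)


def rank_sum_test(
    x, y, alternative: str = "less", exact_max_total: int = 50
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two independent samples.

    ``alternative="less"`` tests whether ``x`` is stochastically smaller
    (left-shifted) relative to ``y``. For pooled sample sizes up to
    ``exact_max_total`` the p-value is exact — P(R_x <= r_obs) under random
    assignment of the pooled midranks, correct under ties; above that a
    normal approximation with tie correction and continuity correction is
    used. A fully tied pooled sample is degenerate and returns p = 0.5.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test: empty sample")
    if alternative == "greater":
        res = rank_sum_test(y, x, "less", exact_max_total)
        return RankSumResult(res.statistic, res.p, x.size, y.size, res.method)

    pooled = np.concatenate([x, y])
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    ranks = _midranks(pooled)
    r_x = float(ranks[:n_x].sum())

    if np.ptp(pooled) == 0.0:
        return RankSumResult(r_x, 0.5, n_x, n_y, "degenerate")

    if n <= exact_max_total:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        r2_obs = int(round(2.0 * r_x))
        p = _exact_ranksum_cdf(ranks2, n_x, r2_obs)
        return RankSumResult(r_x, min(1.0, p), n_x, n_y, "exact")

    mean = n_x * (n + 1) / 2.0
    tie_counts = np.unique(pooled, return_counts=True)[1]
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(r_x, 0.5, n_x, n_y, "degenerate")
    z = (r_x - mean + 0.5) / math.sqrt(var)  # continuity correction toward the tail
    p = float(sps.norm.cdf(z))
    return RankSumResult(r_x, min(1.0, p), n_x, n_y, "normal")
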