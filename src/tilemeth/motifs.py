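"""PWM average-odds scoring and motif enrichment.

A sequence's score for a motif is the arithmetic mean, over every window on
both strands, of the window's likelihood ratio under the PWM versus a
0-order background (uniform 0.25 per base by default). Enrichment of a
positive sequence set against matched controls uses a fixed threshold (the
95th percentile of control scores by default) and a one-sided Fisher's
exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PWM
from .stats import fisher_greater

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return arr


def _window_odds(codes: np.ndarray, ratio: np.ndarray) -> np.ndarray:
    """Odds of every scoreable window on one strand.

    ``ratio`` is the (width, 4) matrix of pwm/background probability ratios;
    windows containing a non-ACGT base are skipped.
    """
    w = ratio.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)  # (n, w)
    valid = (win != 4).all(axis=1)
    if not valid.any():
        return np.empty(0)
    win = win[valid]
    vals = ratio[np.arange(w)[None, :], win]  # (n_valid, w)
    return vals.prod(axis=1)


def average_odds_score(
    seq: str,
    pwm: PWM,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    zero_floor: float = 0.0,
) -> float:
    """Average odds score of a sequence under a PWM.

    Mean over all windows on both strands of
    ``prod_j pwm_j(base_j) / background(base_j)``. ``zero_floor`` > 0
    replaces zero PWM probabilities before scoring (the enrichment pipeline
    uses 1e-4; the default keeps toy matrices exact). The window odds are
    accumulated in sorted order, which makes the score exactly invariant
    under reverse complementation of the sequence.
    """
    seq = seq.upper()
    mat = pwm.array()
    if zero_floor > 0.0:
        mat = np.maximum(mat, zero_floor)
    if len(seq) < pwm.width:
        raise ValueError(
            f"sequence ({len(seq)} bp) shorter than PWM {pwm.motif_id} ({pwm.width} bp)"
        )
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    ratio = mat / bg[None, :]
    fwd = _window_odds(_encode(seq), ratio)
    rev = _window_odds(_encode(reverse_complement(seq)), ratio)
    odds = np.concatenate([fwd, rev])
    if odds.size == 0:
        raise ValueError("sequence has no scoreable window (all contain N)")
    odds.sort()
    return float(odds.sum() / odds.size)


def score_sequences(
    seqs: Mapping[str, str],
    pwms: Sequence[PWM],
    background: Sequence[float] = UNIFORM_BACKGROUND,
    zero_floor: float = 0.0,
) -> pd.DataFrame:
    """Score every sequence against every PWM; rows = sequence ids, columns
    = motif ids. Sequences with no scoreable window are dropped with a
    counted warning."""
    dropped = 0
    rows: dict[str, dict[str, float]] = {}
    for sid, seq in seqs.items():
        row = {}
        try:
            for pwm in pwms:
                row[pwm.motif_id] = average_odds_score(seq, pwm, background, zero_floor)
        except ValueError:
            dropped += 1
            continue
        rows[sid] = row
    if dropped:
        warnings.warn(f"dropped {dropped} unscoreable sequence(s)")
    return pd.DataFrame.from_dict(rows, orient="index")[[p.motif_id for p in pwms]]


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    cell_type: str
    threshold: float
    pos_above: int
    pos_below: int
    ctrl_above: int
    ctrl_below: int
    p: float
    degenerate: bool = False


def motif_enrichment_test(
    positive_seqs: Mapping[str, str],
    control_seqs: Mapping[str, str],
    pwms: Sequence[PWM],
    cell_type: str = "",
    threshold_policy: str = "ctrl-q95",
    background: Sequence[float] = UNIFORM_BACKGROUND,
    zero_floor: float = 1e-4,
) -> list[MotifEnrichment]:
    """Fisher enrichment of positive sequences scoring above a control-set
    threshold, per motif.

    The default policy sets the threshold at the 95th percentile of the
    control scores (upper interpolation, deterministic); a sequence counts
    as "above" when its score exceeds the threshold strictly. When every
    score is identical the test is degenerate and p = 1.
    """
    if not control_seqs:
        raise ValueError("need at least one control sequence")
    if threshold_policy != "ctrl-q95":
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    pos = score_sequences(positive_seqs, pwms, background, zero_floor)
    ctrl = score_sequences(control_seqs, pwms, background, zero_floor)
    out: list[MotifEnrichment] = []
    for pwm in pwms:
        ps = pos[pwm.motif_id].to_numpy()
        cs = ctrl[pwm.motif_id].to_numpy()
        thr = float(np.quantile(cs, 0.95, method="higher"))
        pos_above = int((ps > thr).sum())
        ctrl_above = int((cs > thr).sum())
        table = (
            (pos_above, ps.size - pos_above),
            (ctrl_above, cs.size - ctrl_above),
        )
        if np.ptp(np.concatenate([ps, cs])) == 0.0:
            out.append(
                MotifEnrichment(pwm.motif_id, cell_type, thr, *table[0], *table[1], 1.0, True)
            )
            continue
        _, p = fisher_greater(table)
        out.append(MotifEnrichment(pwm.motif_id, cell_type, thr, *table[0], *table[1], p))
    return out


def enrichment_matrix(
    enrichments: Sequence[MotifEnrichment], normalize: str = "none"
) -> pd.DataFrame:
    """Motif x cell matrix of -log10 enrichment p-values.

    ``normalize="row_max"`` divides each motif's row by its maximum so the
    strongest cell is 1. Missing (motif, cell) combinations stay NaN.
    """
    if normalize not in ("none", "row_max"):
        raise ValueError(f"unknown normalization {normalize!r}")
    motifs = sorted({e.motif_id for e in enrichments})
    cells = sorted({e.cell_type for e in enrichments})
    mat = pd.DataFrame(np.nan, index=motifs, columns=cells)
    for e in enrichments:
        mat.loc[e.motif_id, e.cell_type] = -math.log10(max(e.p, 1e-300))
    if normalize == "row_max":
        row_max = mat.max(axis=1)
        mat = mat.div(row_max.where(row_max > 0, 1.0), axis=0)
    return mat
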