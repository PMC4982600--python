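"""Interval-level ROC/AUC benchmarking of PWMs with MCC threshold optimization.

A ChIP-seq interval counts as true positive at a threshold when its best
matrix-similarity score (over all windows, both strands) reaches the
threshold; a background (DNase) interval reaching it counts as false
positive.  Thresholds sweep every distinct observed score from 1.0 down to a
floor (default 0.5), the curve is closed to (1, 1), and the area under it is
taken by the trapezoid rule — which, when all scores lie above the floor,
equals the Mann-Whitney pair-counting statistic P(pos > neg) + P(pos = neg)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .pwm import PWM, best_score

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "ThresholdScan",
    "interval_best_scores",
    "roc_curve",
    "mcc",
    "optimize_mcc",
    "rank_pwm_library",
]

Score = float | None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (fpr, tpr) along the sweep
    auc: float
    thresholds: tuple[float, ...]


@dataclass(frozen=True)
class ThresholdScan:
    thresholds: tuple[float, ...]  # descending
    mcc_values: tuple[float, ...]
    optimal_threshold: float
    optimal_mcc: float


def interval_best_scores(
    pwm: PWM,
    intervals: Sequence[GenomicInterval],
    genome: Mapping[str, str],
) -> list[Score]:
    """Best MSS per interval sequence; ``None`` when no window is scorable."""
    out: list[Score] = []
    for iv in intervals:
        try:
            chrom_seq = genome[iv.chrom]
        except KeyError:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end}: unknown chromosome") from None
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends beyond "
                f"chromosome end ({len(chrom_seq)} bp)"
            )
        out.append(best_score(pwm, str(chrom_seq[iv.start : iv.end])))
    return out


def _as_array(scores: Sequence[Score]) -> np.ndarray:
    """Scores as floats with absent values mapped to -inf (below every threshold)."""
    return np.array([-np.inf if s is None else float(s) for s in scores])


def _sweep_thresholds(pos: np.ndarray, neg: np.ndarray, floor: float) -> np.ndarray:
    observed = np.concatenate([pos, neg])
    observed = observed[(observed >= floor) & (observed <= 1.0)]
    return np.unique(np.concatenate([observed, [floor]]))[::-1]


def roc_curve(
    pos_scores: Sequence[Score],
    neg_scores: Sequence[Score],
    floor: float = 0.5,
    close: bool = True,
) -> ROCCurve:
    """ROC curve over descending distinct observed scores in [floor, 1.0].

    ``close=True`` (default) appends the (1, 1) endpoint so the area spans
    the full FPR range even when the sweep stops at the floor.
    """
    if not len(pos_scores) or not len(neg_scores):
        raise ValueError("both positive and negative score sets must be nonempty")
    pos, neg = _as_array(pos_scores), _as_array(neg_scores)
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    thresholds = _sweep_thresholds(pos, neg, floor)
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        pts.append((fpr, tpr))
    if close and pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    xs, ys = zip(*pts)
    auc = float(np.trapezoid(ys, xs))
    return ROCCurve(tuple(pts), auc, tuple(float(t) for t in thresholds))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when a marginal is zero."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def optimize_mcc(
    pos_scores: Sequence[Score],
    neg_scores: Sequence[Score],
    floor: float = 0.5,
) -> ThresholdScan:
    """MCC at every distinct observed score in [floor, 1.0]; ties break stricter.

    Intervals with no scorable window always count against the positive call
    (false negative / true negative).
    """
    if not len(pos_scores) or not len(neg_scores):
        raise ValueError("both positive and negative score sets must be nonempty")
    pos, neg = _as_array(pos_scores), _as_array(neg_scores)
    thresholds = _sweep_thresholds(pos, neg, floor)
    values: list[float] = []
    best_t, best_v = float(thresholds[0]), -np.inf
    for t in thresholds:
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        v = mcc(ConfusionCounts(tp, fp, len(neg) - fp, len(pos) - tp))
        values.append(v)
        if v > best_v:  # strict: earlier (higher) threshold wins ties
            best_v, best_t = v, float(t)
    return ThresholdScan(
        tuple(float(t) for t in thresholds), tuple(values), best_t, float(best_v)
    )


def rank_pwm_library(
    library: Sequence[PWM],
    pos_intervals: Sequence[GenomicInterval],
    neg_intervals: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    floor: float = 0.5,
) -> pd.DataFrame:
    """AUC of every matrix against the positive/background interval sets.

    Returns a frame with columns ``pwm_id`` and ``auc`` sorted by descending
    AUC, ties broken lexicographically by matrix id.
    """
    if not library:
        raise ValueError("matrix library is empty")
    rows = []
    for pwm in library:
        pos = interval_best_scores(pwm, pos_intervals, genome)
        neg = interval_best_scores(pwm, neg_intervals, genome)
        rows.append({"pwm_id": pwm.id, "auc": roc_curve(pos, neg, floor).auc})
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["auc", "pwm_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
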