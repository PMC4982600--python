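"""Enhancer-promoter distance analysis: nearest-enhancer gaps, subsampled
distance distributions for two enhancer groups, and a Mann-Whitney rank test
that stays numerically meaningful at astronomically small p-values.

Distances here are edge-to-edge gaps (promoter start minus enhancer end for
upstream candidates, enhancer start minus promoter end downstream), zero on
overlap — deliberately a different convention from the start-to-start CCAAT
spacing in :mod:`motifarch.ccaat`.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceRecord",
    "ResamplingPlan",
    "RankTestResult",
    "nearest_enhancer_distance",
    "nearest_distances",
    "resample_distance_distributions",
    "mann_whitney",
]


@dataclass(frozen=True)
class DistanceRecord:
    promoter: GenomicInterval
    enhancer: GenomicInterval
    distance: int  # edge-to-edge gap, >= 0; 0 on overlap
    side: str  # "upstream" | "downstream"


@dataclass(frozen=True)
class ResamplingPlan:
    """Repetition count and per-repetition subgroup size for group comparison."""

    n_samples: int = 1000
    subgroup_size: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.subgroup_size < 1:
            raise ValueError("n_samples and subgroup_size must be positive")


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    z: float
    p_two_sided: float
    log10_p: float
    n_x: int
    n_y: int


def _gap(promoter: GenomicInterval, enhancer: GenomicInterval) -> tuple[int, str]:
    if enhancer.end <= promoter.start:
        return promoter.start - enhancer.end, "upstream"
    if enhancer.start >= promoter.end:
        return enhancer.start - promoter.end, "downstream"
    return 0, "upstream" if enhancer.start < promoter.start else "downstream"


def nearest_enhancer_distance(
    promoter: GenomicInterval, enhancers: Sequence[GenomicInterval]
) -> DistanceRecord | None:
    """Closest same-chromosome enhancer, up- or downstream; ties go upstream.

    Returns ``None`` when no enhancer shares the promoter's chromosome.
    """
    best: DistanceRecord | None = None
    for e in enhancers:
        if e.chrom != promoter.chrom:
            continue
        d, side = _gap(promoter, e)
        if best is None or d < best.distance or (
            d == best.distance and side == "upstream" and best.side == "downstream"
        ):
            best = DistanceRecord(promoter, e, d, side)
    return best


class _EnhancerIndex:
    """Per-chromosome sorted enhancer edges for O(log n) nearest-gap queries."""

    def __init__(self, enhancers: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for e in enhancers:
            grouped.setdefault(e.chrom, []).append(e)
        for chrom, items in grouped.items():
            items.sort(key=lambda iv: iv.start)
            starts = [iv.start for iv in items]
            # running max of ends over the sorted-by-start prefix handles nesting
            ends: list[int] = []
            m = -1
            for iv in items:
                m = max(m, iv.end)
                ends.append(m)
            self._by_chrom[chrom] = (starts, ends)

    def nearest(self, promoter: GenomicInterval) -> int | None:
        edges = self._by_chrom.get(promoter.chrom)
        if edges is None:
            return None
        starts, ends = edges
        k = bisect_right(starts, promoter.end - 1)
        best: int | None = None
        if k < len(starts):  # nearest strictly-downstream start
            best = starts[k] - promoter.end
        if k > 0:
            up = max(0, promoter.start - ends[k - 1])
            if ends[k - 1] > promoter.start:  # an earlier-starting enhancer overlaps
                up = 0
            best = up if best is None else min(best, up)
        return best


def nearest_distances(
    promoters: Sequence[GenomicInterval], enhancers: Sequence[GenomicInterval]
) -> list[int | None]:
    """Nearest edge-to-edge gap per promoter (``None`` when no candidate exists)."""
    idx = _EnhancerIndex(enhancers)
    return [idx.nearest(p) for p in promoters]


def resample_distance_distributions(
    promoters: Sequence[GenomicInterval],
    group_a: Sequence[GenomicInterval],
    group_b: Sequence[GenomicInterval],
    plan: ResamplingPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled nearest-distance multisets under repeated equal-size subsampling.

    Per repetition, ``subgroup_size`` enhancers are drawn without replacement
    from each group and every promoter's nearest distance to each subgroup is
    recorded; records pool across repetitions.  Promoters with no
    same-chromosome candidate in a subgroup are skipped for that repetition.
    """
    for name, group in (("A", group_a), ("B", group_b)):
        if plan.subgroup_size > len(group):
            raise ValueError(
                f"subgroup size {plan.subgroup_size} exceeds group {name} "
                f"size {len(group)}"
            )
    rng = np.random.default_rng(plan.seed)
    pools: list[list[int]] = [[], []]
    for _ in range(plan.n_samples):
        for gi, group in enumerate((group_a, group_b)):
            chosen = rng.choice(len(group), size=plan.subgroup_size, replace=False)
            subgroup = [group[i] for i in chosen]
            pools[gi].extend(
                d for d in nearest_distances(promoters, subgroup) if d is not None
            )
    return np.asarray(pools[0]), np.asarray(pools[1])


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test via the tie-corrected normal approximation.

    U is the number of (x, y) pairs with x > y plus half the ties, computed
    from midranks.  The p-value is evaluated in log space (continuity
    corrected), so extreme departures yield a finite ``log10_p`` even when
    the linear p underflows; the linear value is floored at the smallest
    positive double.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        logger.warning("degenerate pooled ranks (all values tied); p = 1")
        return RankTestResult(float(u), 0.0, 1.0, 0.0, n1, n2)
    cc = 0.5 if u != mu else 0.0
    z = (u - mu - math.copysign(cc, u - mu)) / math.sqrt(var)
    log_p = math.log(2.0) + float(log_ndtr(-abs(z)))
    log_p = min(log_p, 0.0)
    p = math.exp(log_p) if log_p > math.log(5e-324) else 5e-324
    return RankTestResult(float(u), float(z), p, log_p / math.log(10.0), n1, n2)
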