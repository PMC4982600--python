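"""Motif co-occurrence statistics: presence classes, 2x2 tables, Fisher's exact
test with the conditional-MLE odds ratio, and the mutual-exclusivity summary.

The conditional maximum-likelihood odds ratio is the value psi solving the
score equation E[a | margins, psi] = a under the noncentral hypergeometric
distribution of the top-left cell given all four margins — the estimate
reported by Fisher's exact test in R, which shrinks toward 1 relative to the
cross-product ratio ad/(bc).  The two-sided p-value sums the point
probabilities of all tables (at psi = 1) no more probable than the observed
one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "MotifPresence",
    "ContingencyTable",
    "FisherResult",
    "SetTally",
    "ExclusivityScatter",
    "classify_motif_presence",
    "fisher_exact",
    "odds",
    "conditional_mle_or",
    "exclusivity_scatter",
]


class MotifPresence(Enum):
    AP1_ONLY = "ap1_only"
    NFY_ONLY = "nfy_only"
    BOTH = "both"
    NEITHER = "neither"


def classify_motif_presence(
    ap1_score: float | None,
    nfy_score: float | None,
    ap1_thr: float,
    nfy_thr: float,
) -> MotifPresence:
    """Classify one interval by which motif scores reach their thresholds."""
    has_ap1 = ap1_score is not None and ap1_score >= ap1_thr
    has_nfy = nfy_score is not None and nfy_score >= nfy_thr
    if has_ap1 and has_nfy:
        return MotifPresence.BOTH
    if has_ap1:
        return MotifPresence.AP1_ONLY
    if has_nfy:
        return MotifPresence.NFY_ONLY
    return MotifPresence.NEITHER


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts laid out as rows (e.g. proximal/distal) x columns (motif+/motif-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FisherResult:
    or_mle: float | None  # conditional MLE; None for degenerate margins
    p_two_sided: float
    sample_or: float | None  # cross-product a*d/(b*c); None on zero denominator


def odds(t: ContingencyTable) -> tuple[float | None, float | None, float | None]:
    """Row odds a/b and c/d and their ratio; ``None`` with a warning on zero denominators."""
    o1 = t.a / t.b if t.b else None
    o2 = t.c / t.d if t.d else None
    if o1 is None or o2 is None:
        logger.warning("zero denominator in odds computation for table %s", t)
        return o1, o2, None
    if o2 == 0:
        logger.warning("second-row odds are zero; ratio undefined for table %s", t)
        return o1, o2, None
    return o1, o2, o1 / o2


def _nchg_log_pmf(support: np.ndarray, m1: int, m2: int, n1: int, log_psi: float) -> np.ndarray:
    """Log pmf of Fisher's noncentral hypergeometric distribution over ``support``.

    ``m1``/``m2`` are the row totals and ``n1`` the first column total; the
    variable is the top-left cell a.
    """
    logw = (
        gammaln(m1 + 1) - gammaln(support + 1) - gammaln(m1 - support + 1)
        + gammaln(m2 + 1) - gammaln(n1 - support + 1) - gammaln(m2 - n1 + support + 1)
        + support * log_psi
    )
    return logw - np.logaddexp.reduce(logw)


def conditional_mle_or(t: ContingencyTable, tol: float = 1e-10) -> float | None:
    """Conditional MLE odds ratio given all margins, by bisection on log psi.

    Returns ``inf``/``0`` when the observed cell sits at the edge of its
    support (b or c zero versus a or d zero), and ``None`` when a margin is
    zero so the table carries no information about association.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    m1, m2 = a + b, c + d
    n1 = a + c
    if m1 == 0 or m2 == 0 or n1 == 0 or b + d == 0:
        return None
    lo_s, hi_s = max(0, n1 - m2), min(n1, m1)
    if lo_s == hi_s:
        return None
    if a == hi_s:
        return math.inf
    if a == lo_s:
        return 0.0
    support = np.arange(lo_s, hi_s + 1)

    def mean_minus_a(log_psi: float) -> float:
        logp = _nchg_log_pmf(support, m1, m2, n1, log_psi)
        return float(np.exp(logp) @ support) - a

    lo, hi = -1.0, 1.0
    while mean_minus_a(lo) > 0:
        lo *= 2
        if lo < -500:
            return 0.0
    while mean_minus_a(hi) < 0:
        hi *= 2
        if hi > 500:
            return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_minus_a(mid) < 0:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def fisher_exact(t: ContingencyTable) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p sums hypergeometric point probabilities <= that of the
    observed table; the odds ratio is the conditional MLE.  Tables with a
    zero margin are degenerate: p = 1 and no odds ratio.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return FisherResult(None, 1.0, _sample_or(t))
    p = float(stats.fisher_exact(t.as_array(), alternative="two-sided").pvalue)
    return FisherResult(conditional_mle_or(t), min(p, 1.0), _sample_or(t))


def _sample_or(t: ContingencyTable) -> float | None:
    if t.b * t.c == 0:
        return math.inf if t.a * t.d > 0 else None
    return (t.a * t.d) / (t.b * t.c)


# ---------------------------------------------------------------------------
# Mutual-exclusivity summary


@dataclass(frozen=True)
class SetTally:
    """Per-set motif-presence counts (exclusive classes; ``both`` counted once)."""

    label: str
    ap1_only: int
    nfy_only: int
    both: int
    neither: int

    @property
    def total(self) -> int:
        return self.ap1_only + self.nfy_only + self.both + self.neither


@dataclass(frozen=True)
class ExclusivityScatter:
    points: tuple[tuple[float, float], ...]  # (% AP-1, % NF-Y) per set
    r: float
    definition: str


_DEFINITIONS = ("inclusive", "exclusive", "either_only")


def exclusivity_scatter(
    tallies: Sequence[SetTally], definition: str = "inclusive"
) -> ExclusivityScatter:
    """Per-set AP-1 versus NF-Y motif percentages and their Pearson correlation.

    Percentage conventions:
      * ``inclusive`` — x = (ap1_only + both) / total, y = (nfy_only + both) / total;
      * ``exclusive`` — x = ap1_only / total, y = nfy_only / total;
      * ``either_only`` — denominators restricted to intervals with >= 1 motif.
    """
    if definition not in _DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}; choose from {_DEFINITIONS}")
    if len(tallies) < 3:
        raise ValueError("need at least 3 sets for a correlation")
    points: list[tuple[float, float]] = []
    for t in tallies:
        if definition == "either_only":
            denom = t.ap1_only + t.nfy_only + t.both
        else:
            denom = t.total
        if denom == 0:
            raise ValueError(f"set {t.label}: empty denominator")
        if definition == "exclusive":
            x, y = t.ap1_only, t.nfy_only
        else:
            x, y = t.ap1_only + t.both, t.nfy_only + t.both
        points.append((100.0 * x / denom, 100.0 * y / denom))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance across sets; correlation undefined")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return ExclusivityScatter(tuple(points), r, definition)
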