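"""TRANSFAC-format PWM parsing and MATCH-style matrix-similarity scanning.

A position weight matrix is stored as an L x 4 table of base counts over the
alphabet A, C, G, T.  Scoring follows the MATCH information-weighted scheme:
each position carries an information value

    I(i) = sum_b f(i, b) * ln(4 * f(i, b))        (0 * ln 0 := 0)

and a window of bases b_1..b_L scores

    Current = sum_i I(i) * f(i, b_i)
    MSS     = (Current - Min) / (Max - Min)

where Max and Min take the per-position maximum and minimum frequencies, so
the consensus window scores exactly 1.0 and the anti-consensus exactly 0.0.
Both strands are scanned; minus-strand hits are reported at the forward-strand
start of the window they cover.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

__all__ = [
    "PWM",
    "MatchConfig",
    "MotifHit",
    "ALPHABET",
    "reverse_complement",
    "parse_transfac",
    "write_transfac",
    "information_vector",
    "score_window",
    "scan_sequence",
    "best_score",
    "core_positions",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f ln(4 f), with 0 ln 0 = 0."""
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=1)


@dataclass(frozen=True)
class PWM:
    """Positional base-count matrix with derived frequencies and information vector."""

    id: str
    counts: np.ndarray  # L x 4 nonnegative, columns A C G T
    pseudocount: float = 0.0
    name: str = ""
    freqs: np.ndarray = field(init=False, repr=False)
    info: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] == 0:
            raise ValueError(f"matrix {self.id}: counts must be L x 4, L >= 1")
        if (counts < 0).any():
            raise ValueError(f"matrix {self.id}: negative counts")
        row_sums = counts.sum(axis=1)
        if self.pseudocount == 0 and (row_sums == 0).any():
            raise ValueError(f"matrix {self.id}: zero row sum")
        object.__setattr__(self, "counts", counts)
        freqs = (counts + self.pseudocount) / (
            row_sums + 4.0 * self.pseudocount
        )[:, None]
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "info", information_vector(freqs))

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.freqs.argmax(axis=1))

    @property
    def is_degenerate(self) -> bool:
        """True when every position is uniform, so Max == Min in the MSS formula."""
        weighted = self.info[:, None] * self.freqs
        return bool(np.isclose(weighted.max(axis=1).sum(), weighted.min(axis=1).sum()))


@dataclass(frozen=True)
class MatchConfig:
    """Scanning thresholds: MSS floor, CSS floor, and the count pseudocount."""

    mss_threshold: float = 0.5
    css_threshold: float = 0.0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mss_threshold <= 1.0 and 0.0 <= self.css_threshold <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class MotifHit:
    position: int  # forward-strand start of the covered window
    strand: str
    mss: float
    css: float | None = None


# ---------------------------------------------------------------------------
# TRANSFAC flat-file I/O

_ROW_RE = re.compile(r"^(\d{1,2})\s+(.*)$")


def parse_transfac(text: str, pseudocount: float = 0.0) -> list[PWM]:
    """Parse TRANSFAC matrix flat-file content into PWMs.

    Records are delimited by ``//``; ``ID``/``AC``/``NA`` header lines are
    honored, ``P0``/``PO`` column headers and ``XX`` separators skipped, and
    numbered rows ``01``, ``02``, ... carry four count columns ordered
    A C G T (a trailing consensus letter is tolerated).  A record missing its
    terminating ``//`` at end of file is still parsed.
    """
    pwms: list[PWM] = []
    ident = ""
    name = ""
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal ident, name, rows
        if rows:
            pwms.append(
                PWM(ident or f"matrix_{len(pwms) + 1}", np.array(rows), pseudocount, name)
            )
        ident, name, rows = "", "", []

    for raw in text.splitlines():
        line = raw.rstrip()
        if line.startswith("//"):
            flush()
            continue
        if not line or line.startswith("XX"):
            continue
        key = line[:2]
        if key in ("P0", "PO"):
            continue
        if key in ("ID", "AC", "NA"):
            value = line[2:].strip()
            if key == "NA":
                name = value
            elif not ident or key == "ID":
                ident = value
            continue
        m = _ROW_RE.match(line)
        if m:
            tokens = m.group(2).split()
            numeric = tokens[:4]
            if len(numeric) < 4:
                raise ValueError(
                    f"matrix {ident or '<unnamed>'}: row {m.group(1)} has "
                    f"{len(numeric)} count columns, expected 4"
                )
            try:
                rows.append([float(t) for t in numeric])
            except ValueError:
                raise ValueError(
                    f"matrix {ident or '<unnamed>'}: non-numeric count in row "
                    f"{m.group(1)}: {line!r}"
                ) from None
    flush()
    return pwms


def write_transfac(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.id}\nXX\n")
            if pwm.name:
                fh.write(f"NA {pwm.name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.counts, start=1):
                cells = "  ".join(f"{v:7.2f}" for v in row)
                fh.write(f"{i:02d}  {cells}  {pwm.consensus[i - 1]}\n")
            fh.write("XX\n//\n")


# ---------------------------------------------------------------------------
# Scoring


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to 0..3 indices; anything outside ACGT becomes 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """MSS of every length-L window of an encoded sequence; NaN where unscorable."""
    L = len(pwm)
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    weighted = pwm.info[:, None] * pwm.freqs  # L x 4
    max_score = weighted.max(axis=1).sum()
    min_score = weighted.min(axis=1).sum()
    padded = np.hstack([weighted, np.full((L, 1), np.nan)])  # col 4 poisons N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    current = padded[np.arange(L)[None, :], windows].sum(axis=1)
    if np.isclose(max_score, min_score):
        logger.warning("matrix %s is fully uniform; every window scores 1.0", pwm.id)
        return np.where(np.isnan(current), np.nan, 1.0)
    return (current - min_score) / (max_score - min_score)


def score_window(pwm: PWM, window: str) -> float:
    """MSS of a single window; the window length must equal the matrix length."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)} ({pwm.id})"
        )
    codes = _encode(window)
    if (codes == 4).any():
        raise ValueError(f"window contains non-ACGT characters: {window!r}")
    return float(_window_scores(pwm, codes)[0])


def _core_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray | None:
    """CSS of every window: MSS restricted to the 5 most informative consecutive positions."""
    core = core_positions(pwm)
    if core is None:
        return None
    s = core[0]
    sub = PWM(pwm.id + "|core", pwm.counts[s : s + 5], pwm.pseudocount)
    L = len(pwm)
    n = codes.size - L + 1
    core_scores = _window_scores(sub, codes)
    return core_scores[s : s + n]


def scan_sequence(pwm: PWM, seq: str, cfg: MatchConfig = MatchConfig()) -> list[MotifHit]:
    """Scan both strands, returning hits with MSS >= the configured threshold.

    Windows containing non-ACGT characters are skipped.  Minus-strand hits are
    mapped back to forward coordinates: a hit at offset ``j`` of the reverse
    complement covers forward positions ``[n - L - j, n - j)``.
    """
    L = len(pwm)
    n = len(seq)
    if n < L:
        return []
    hits: list[MotifHit] = []
    use_css = cfg.css_threshold > 0.0 and len(pwm) >= 5
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = _encode(s)
        scores = _window_scores(pwm, codes)
        css = _core_scores(pwm, codes) if use_css else None
        for j in np.flatnonzero(~np.isnan(scores) & (scores >= cfg.mss_threshold)):
            c = float(css[j]) if css is not None and not np.isnan(css[j]) else None
            if use_css and (c is None or c < cfg.css_threshold):
                continue
            pos = int(j) if strand == "+" else n - L - int(j)
            hits.append(MotifHit(pos, strand, float(scores[j]), c))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def best_score(pwm: PWM, seq: str) -> float | None:
    """Maximum MSS over all scorable windows of both strands; None when none are."""
    L = len(pwm)
    if len(seq) < L:
        return None
    maxima: list[float] = []
    for s in (seq, reverse_complement(seq)):
        scores = _window_scores(pwm, _encode(s))
        finite = scores[~np.isnan(scores)]
        if finite.size:
            maxima.append(float(finite.max()))
    return max(maxima) if maxima else None


def core_positions(pwm: PWM) -> tuple[int, int] | None:
    """Start/end (half-open) of the 5 consecutive positions maximizing summed information.

    Ties break toward the smallest start; matrices shorter than 5 have no core.
    """
    L = len(pwm)
    if L < 5:
        return None
    sums = np.convolve(pwm.info, np.ones(5), mode="valid")
    s = int(np.argmax(sums))  # argmax returns the first maximum
    return s, s + 5
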