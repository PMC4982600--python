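"""Genomic interval model, BED/narrowPeak I/O, overlap algebra and TSS-relative classification.

All coordinates are 0-based half-open (BED convention).  Overlap between two
intervals means at least one shared base pair.  The central classification
splits peaks into *proximal* regions (overlapping the 1 kb window upstream of
an annotated TSS, or the first exon), *distal* regions (overlapping neither
that window nor any transcription unit), and *excluded* regions (gene-body
only), which stand in for promoters and enhancer candidates respectively.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionClass",
    "ColocalizationPartition",
    "UnionGroups",
    "read_narrowpeak",
    "write_bed",
    "read_bed12",
    "write_bed12",
    "classify_region",
    "classify_regions",
    "RegionClassifier",
    "merge_blocks",
    "partition_by_overlap",
    "subtract_overlapping",
    "build_union_groups",
    "overlap_fraction_report",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` with optional peak metadata.

    ``summit_offset`` is the narrowPeak point-source offset (column 10),
    measured in bp from ``start``; ``None`` when absent (``-1`` in the file).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Transcription unit with exon structure, as read from BED12.

    The first exon is the 5'-most exon on the coding strand, i.e. the first
    block for ``+`` genes and the last block for ``-`` genes.  The TSS is
    ``tx_start`` on ``+`` and ``tx_end`` on ``-``.
    """

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"gene {self.symbol}: exon lists empty or unequal")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.symbol}: exon [{s},{e}) outside body")
            if s < prev_end and (s, e) != (self.exon_starts[0], self.exon_ends[0]):
                raise ValueError(f"gene {self.symbol}: exons unsorted/overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def first_exon(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.exon_starts[0], self.exon_ends[0]
        return self.exon_starts[-1], self.exon_ends[-1]

    def proximal_window(self, upstream: int = 1000) -> tuple[int, int]:
        """Strand-aware union bounds of the upstream window and first exon.

        Returns the upstream window ``[TSS - upstream, TSS)`` (mirrored for
        ``-`` strand) clipped at zero; the first exon is contiguous with the
        TSS, so window + first exon form one half-open span.
        """
        fe_start, fe_end = self.first_exon
        if self.strand == "+":
            return max(0, self.tx_start - upstream), fe_end
        return fe_start, self.tx_end + upstream


class RegionClass(Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"
    EXCLUDED = "excluded"


# ---------------------------------------------------------------------------
# I/O


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"line {lineno}: non-integer {what}: {token!r}") from None


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read a narrowPeak (BED6+4) or plain BED3/BED6 file.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    Malformed coordinates raise :class:`ValueError` naming the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if end <= start or start < 0:
                raise ValueError(
                    f"line {lineno}: invalid coordinates {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            summit: int | None = None
            if len(fields) >= 10:
                raw = _parse_int(fields[9], "summit offset", lineno)
                summit = raw if raw >= 0 else None
            out.append(
                GenomicInterval(chrom, start, end, name, score, strand, summit)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, narrowpeak: bool = False) -> None:
    """Write intervals as BED6 (or narrowPeak with signal/p/q placeholders)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".",
                    f"{score:g}", iv.strand]
            if narrowpeak:
                summit = -1 if iv.summit_offset is None else iv.summit_offset
                cols += [f"{score:g}", "-1", "-1", str(summit)]
            fh.write("\t".join(cols) + "\n")


def read_bed12(path) -> list[GeneModel]:
    """Read BED12 gene models (RefSeq-style)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 12:
                raise ValueError(f"line {lineno}: BED12 requires 12 columns")
            chrom, start, end = f[0], _parse_int(f[1], "start", lineno), _parse_int(f[2], "end", lineno)
            name, strand = f[3], f[5]
            n_blocks = _parse_int(f[9], "blockCount", lineno)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"line {lineno}: block list length mismatch")
            exon_starts = tuple(start + o for o in offsets)
            exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
            genes.append(GeneModel(chrom, strand, start, end, exon_starts, exon_ends, name))
    return genes


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offsets = ",".join(str(s - g.tx_start) for s in g.exon_starts)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.tx_start), str(g.tx_end), g.symbol or ".",
                        "0", g.strand, str(g.tx_start), str(g.tx_end), "0",
                        str(len(g.exon_starts)), sizes, offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Proximal / distal classification


class RegionClassifier:
    """Index gene models for repeated TSS-relative interval classification."""

    def __init__(self, genes: Sequence[GeneModel], upstream: int = 1000):
        self.upstream = upstream
        self._proximal: dict[str, IntervalTree] = {}
        self._body: dict[str, IntervalTree] = {}
        self._warned: set[str] = set()
        for g in genes:
            lo, hi = g.proximal_window(upstream)
            if lo < hi:
                self._proximal.setdefault(g.chrom, IntervalTree()).addi(lo, hi)
            self._body.setdefault(g.chrom, IntervalTree()).addi(g.tx_start, g.tx_end)

    def classify(self, iv: GenomicInterval) -> RegionClass:
        if iv.chrom not in self._body:
            if iv.chrom not in self._warned:
                logger.warning(
                    "chromosome %s absent from annotation; classifying as distal",
                    iv.chrom,
                )
                self._warned.add(iv.chrom)
            return RegionClass.DISTAL
        if self._proximal.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            return RegionClass.PROXIMAL
        if self._body[iv.chrom].overlap(iv.start, iv.end):
            return RegionClass.EXCLUDED
        return RegionClass.DISTAL


def classify_region(
    iv: GenomicInterval, genes: Sequence[GeneModel], upstream: int = 1000
) -> RegionClass:
    """Classify one interval against gene models.

    Proximal: >= 1 bp overlap with the strand-aware ``[TSS - upstream, TSS)``
    window or the first exon of any gene.  Distal: overlaps neither the
    proximal window nor any transcription unit.  Excluded: gene-body-only
    overlap (beyond the first exon).
    """
    return RegionClassifier(genes, upstream).classify(iv)


def classify_regions(
    intervals: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    upstream: int = 1000,
) -> dict[RegionClass, list[GenomicInterval]]:
    clf = RegionClassifier(genes, upstream)
    out: dict[RegionClass, list[GenomicInterval]] = {c: [] for c in RegionClass}
    for iv in intervals:
        out[clf.classify(iv)].append(iv)
    return out


# ---------------------------------------------------------------------------
# Overlap algebra


def merge_blocks(
    intervals: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, list[GenomicInterval]]]:
    """Merge intervals into maximal overlapping blocks.

    Returns (block span, member intervals) pairs.  Intervals that merely
    touch (``a.end == b.start``) share no base and stay separate.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    blocks: list[tuple[GenomicInterval, list[GenomicInterval]]] = []
    cur: list[GenomicInterval] = []
    cur_end = 0
    for iv in ordered:
        if cur and iv.chrom == cur[0].chrom and iv.start < cur_end:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                blocks.append(
                    (GenomicInterval(cur[0].chrom, cur[0].start, cur_end), cur)
                )
            cur = [iv]
            cur_end = iv.end
    if cur:
        blocks.append((GenomicInterval(cur[0].chrom, cur[0].start, cur_end), cur))
    return blocks


@dataclass(frozen=True)
class ColocalizationPartition:
    """Counts of merged union blocks private to A, shared, or private to B."""

    a_only: int
    both: int
    b_only: int

    @property
    def total(self) -> int:
        return self.a_only + self.both + self.b_only

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total if self.total else 0.0

    @property
    def pct_a_only(self) -> float:
        return self._pct(self.a_only)

    @property
    def pct_both(self) -> float:
        return self._pct(self.both)

    @property
    def pct_b_only(self) -> float:
        return self._pct(self.b_only)


def partition_by_overlap(
    A: Sequence[GenomicInterval],
    B: Sequence[GenomicInterval],
    count: str = "blocks",
) -> ColocalizationPartition:
    """Partition the merged union of two peak sets by source membership.

    Each maximal overlapping block of ``A | B`` counts once: *both* when it
    contains at least one interval from each source, else *a_only*/*b_only*.
    With ``count="records"`` original peak records are tallied instead of
    blocks (shared blocks then contribute their records to *both*).
    """
    if count not in ("blocks", "records"):
        raise ValueError(f"unknown counting mode {count!r}")
    tagged = [(iv, "A") for iv in A] + [(iv, "B") for iv in B]
    ordered = sorted(tagged, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    a_only = both = b_only = 0
    i = 0
    while i < len(ordered):
        chrom = ordered[i][0].chrom
        cur_end = ordered[i][0].end
        sources = set()
        n_records = 0
        j = i
        while j < len(ordered) and ordered[j][0].chrom == chrom and (
            j == i or ordered[j][0].start < cur_end
        ):
            cur_end = max(cur_end, ordered[j][0].end)
            sources.add(ordered[j][1])
            n_records += 1
            j += 1
        unit = 1 if count == "blocks" else n_records
        if sources == {"A", "B"}:
            both += unit
        elif sources == {"A"}:
            a_only += unit
        else:
            b_only += unit
        i = j
    return ColocalizationPartition(a_only, both, b_only)


class _ChromIndex:
    """Merged-block index of a peak set for O(log n) overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for block, _ in merge_blocks(intervals):
            self._starts.setdefault(block.chrom, []).append(block.start)
            self._ends.setdefault(block.chrom, []).append(block.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        ends = self._ends[iv.chrom]
        k = bisect_right(starts, iv.end - 1)  # blocks starting before iv.end
        return k > 0 and ends[k - 1] > iv.start

    def nearest_gap(self, iv: GenomicInterval) -> int | None:
        """Smallest edge-to-edge gap to any block on the same chromosome (0 on overlap)."""
        starts = self._starts.get(iv.chrom)
        if not starts:
            return None
        ends = self._ends[iv.chrom]
        k = bisect_right(starts, iv.start)
        best: int | None = None
        if k > 0:
            best = max(0, iv.start - ends[k - 1])
        if k < len(starts):
            gap = max(0, starts[k] - iv.end)
            if best is None or gap < best:
                best = gap
        return best


def subtract_overlapping(
    A: Sequence[GenomicInterval], B: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Members of A with no >= 1 bp overlap to any member of B, returned whole."""
    idx = _ChromIndex(B)
    return [iv for iv in A if not idx.overlaps(iv)]


@dataclass
class UnionGroups:
    """Disjoint merged-block groups of a pooled two-factor peak collection."""

    fos_only: list[GenomicInterval] = field(default_factory=list)
    inter: list[GenomicInterval] = field(default_factory=list)
    nfyb_only: list[GenomicInterval] = field(default_factory=list)


def build_union_groups(
    fos_sets: Mapping[str, Sequence[GenomicInterval]],
    nfyb_sets: Mapping[str, Sequence[GenomicInterval]],
) -> UnionGroups:
    """Pool per-cell-line peak sets of two factors and group the merged blocks.

    All peaks are merged into maximal overlapping blocks.  A block joins
    *inter* when it is occupied by both factors (in particular when some cell
    line contributes both a first-factor and a second-factor peak to it);
    blocks occupied by only one factor join *fos_only* / *nfyb_only*.  The
    three lists are disjoint and jointly cover every input interval's span.
    """
    pool: list[tuple[GenomicInterval, str]] = []
    for ivs in fos_sets.values():
        pool.extend((iv, "fos") for iv in ivs)
    for ivs in nfyb_sets.values():
        pool.extend((iv, "nfyb") for iv in ivs)
    ordered = sorted(
        range(len(pool)),
        key=lambda i: (pool[i][0].chrom, pool[i][0].start, pool[i][0].end),
    )
    groups = UnionGroups()
    i = 0
    n = len(ordered)
    while i < n:
        first = pool[ordered[i]][0]
        chrom, cur_end = first.chrom, first.end
        factors = set()
        j = i
        while j < n:
            iv, factor = pool[ordered[j]]
            if iv.chrom != chrom or (j > i and iv.start >= cur_end):
                break
            cur_end = max(cur_end, iv.end)
            factors.add(factor)
            j += 1
        block = GenomicInterval(chrom, first.start, cur_end)
        if factors == {"fos", "nfyb"}:
            groups.inter.append(block)
        elif factors == {"fos"}:
            groups.fos_only.append(block)
        else:
            groups.nfyb_only.append(block)
        i = j
    return groups


def overlap_fraction_report(
    A: Sequence[GenomicInterval], B: Sequence[GenomicInterval]
) -> tuple[int, int | None]:
    """Count of A members overlapping B, and that count as an integer percent of |A|.

    The percentage is ``None`` for an empty A.
    """
    idx = _ChromIndex(B)
    n = sum(1 for iv in A if idx.overlaps(iv))
    pct = round(100.0 * n / len(A)) if A else None
    return n, pct
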