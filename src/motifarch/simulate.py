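"""Synthetic genomes, gene annotations and peak sets with planted motif
architecture.

The generator emulates the kind of data the pipeline targets: ChIP-seq-like
peak sets for an AP-1-bound factor and a CCAAT-binding factor, a DNase-like
background set without planted motifs, and a co-activator-like set that
co-localizes with the factor peaks.  Planted content — AP-1 instances drawn
from the bundled synthetic AP-1 matrix, single CCAAT boxes, and CCAAT direct
repeats with spacings drawn from a categorical distribution peaked at 31 bp
with 10-11 bp harmonics plus an LTR-like 24/41 bp class — is recorded in a
truth table so every downstream stage can be checked against ground truth.

One global seed fans out into independent per-component streams
(:class:`numpy.random.SeedSequence` spawning), so adding a generator stage
never perturbs earlier outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GeneModel, write_bed, write_bed12
from .pwm import PWM, reverse_complement
from .synthetic_matrices import NFY_CORE_OFFSET, ap1_pwm, nfy_pwm

__all__ = [
    "GenomeSpec",
    "PlantingSpec",
    "TruthRecord",
    "SyntheticTruth",
    "PROMOTER_SPACING",
    "LTR_SPACING",
    "TABLE4_LIKE_PREVALENCES",
    "generate_genome",
    "write_fasta",
    "generate_annotation",
    "generate_peak_sets",
    "simulate_study",
    "simulate_motif_sets",
    "simulate_ep_dataset",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default CCAAT tandem spacing distribution: dominant 31 bp mode with
#: progressively decreasing 10-11 bp harmonics (41, 52, 63) and an LTR-like
#: 24 bp class.
PROMOTER_SPACING: dict[int, float] = {24: 0.10, 31: 0.45, 41: 0.20, 52: 0.15, 63: 0.10}

#: LTR12-like spacing class: immediately adjacent footprints and one extra turn.
LTR_SPACING: dict[int, float] = {24: 0.55, 41: 0.45}

#: Eight (label, AP-1 prevalence, CCAAT prevalence) study conditions patterned
#: on the observed per-set motif proportions of four cell lines, proximal and
#: distal: AP-1-dominated enhancer-like sets, CCAAT-dominated promoter-like
#: sets, and intermediates.
TABLE4_LIKE_PREVALENCES: tuple[tuple[str, float, float], ...] = (
    ("huvec_p", 0.41, 0.08),
    ("huvec_d", 0.71, 0.005),
    ("helas3_p", 0.13, 0.69),
    ("helas3_d", 0.82, 0.009),
    ("k562_p", 0.04, 0.73),
    ("k562_d", 0.58, 0.22),
    ("gm12878_p", 0.003, 0.77),
    ("gm12878_d", 0.06, 0.45),
)


@dataclass(frozen=True)
class GenomeSpec:
    """Random genome: chromosome lengths, GC content, and the seed."""

    chrom_lengths: Mapping[str, int]
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome required")
        for name, length in self.chrom_lengths.items():
            if length < 10_000:
                raise ValueError(f"chromosome {name}: length {length} < 10 kb")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie strictly between 0 and 1")


@dataclass(frozen=True)
class PlantingSpec:
    """Planted motif content of one peak set.

    ``ap1_prevalence`` / ``ccaat_prevalence`` are the per-peak probabilities
    of receiving an AP-1 instance or CCAAT content; with ``exclusive`` set
    (default) a peak never receives both.  A CCAAT planting is a direct-repeat
    dimer with probability ``dimer_fraction``, its spacing drawn from
    ``dimer_spacing``; otherwise a single box.  AP-1 instances are sampled
    from the synthetic AP-1 matrix, rejected until their matrix-similarity
    score reaches ``min_planted_mss``.
    """

    n_peaks: int = 300
    ap1_prevalence: float = 0.0
    ccaat_prevalence: float = 0.0
    dimer_fraction: float = 0.5
    dimer_spacing: Mapping[int, float] = field(
        default_factory=lambda: dict(PROMOTER_SPACING)
    )
    peak_width_mean: float = 300.0
    peak_width_sd: float = 50.0
    min_peak_width: int = 120
    exclusive: bool = True
    min_planted_mss: float = 0.95
    region: str = "distal"  # "distal" | "proximal"

    def __post_init__(self) -> None:
        for p in (self.ap1_prevalence, self.ccaat_prevalence, self.dimer_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("prevalences must lie in [0, 1]")
        if self.exclusive and self.ap1_prevalence + self.ccaat_prevalence > 1.0:
            raise ValueError(
                "exclusive planting requires ap1_prevalence + ccaat_prevalence <= 1"
            )
        if self.dimer_spacing:
            if min(self.dimer_spacing) < 5:
                raise ValueError("dimer spacings below 5 bp would self-overlap")
            max_delta = max(self.dimer_spacing)
            if self.min_peak_width < max_delta + 25:
                raise ValueError(
                    f"min peak width {self.min_peak_width} too small for dimer "
                    f"spacing {max_delta} (+ flanked instance and margins)"
                )
        if self.region not in ("distal", "proximal"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class TruthRecord:
    set_name: str
    peak_name: str
    chrom: str
    start: int
    end: int
    motif: str | None  # "ap1" | "ccaat_single" | "ccaat_dimer" | None
    strand: str | None
    positions: tuple[int, ...]  # genomic coordinates of planted instances
    delta: int | None  # dimer spacing, when applicable


@dataclass
class SyntheticTruth:
    """Ground truth for every emitted peak plus the per-gene TSS map."""

    records: list[TruthRecord] = field(default_factory=list)
    tss: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = asdict(r)
            row["positions"] = ",".join(map(str, r.positions))
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def by_set(self, set_name: str) -> list[TruthRecord]:
        return [r for r in self.records if r.set_name == set_name]


# ---------------------------------------------------------------------------
# Genome and annotation


def generate_genome(spec: GenomeSpec) -> dict[str, str]:
    """I.i.d. random genome at the requested GC content, deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out: dict[str, str] = {}
    for name, length in spec.chrom_lengths.items():
        codes = rng.choice(4, size=length, p=probs)
        out[name] = BASES[codes].tobytes().decode("ascii")
    return out


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_annotation(
    genome: Mapping[str, str],
    n_genes: int = 60,
    seed: int = 0,
    gene_length: tuple[int, int] = (2000, 5000),
    stride: int = 20_000,
    margin: int = 3000,
) -> tuple[list[GeneModel], SyntheticTruth]:
    """Non-overlapping multi-exon genes on both strands, evenly strided.

    Genes are laid down one per ``stride`` window with random jitter, leaving
    intergenic space for distal peak placement; the TSS of every gene is
    recorded in the returned truth object.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    truth = SyntheticTruth()
    genes: list[GeneModel] = []
    chroms = list(genome)
    slots: list[tuple[str, int]] = []
    for chrom in chroms:
        n_slots = (len(genome[chrom]) - 2 * margin) // stride
        slots.extend((chrom, margin + i * stride) for i in range(n_slots))
    if len(slots) < n_genes:
        raise ValueError(
            f"genome too small for {n_genes} genes at stride {stride}"
        )
    for gi, (chrom, anchor) in enumerate(slots[:n_genes]):
        glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
        jitter = int(rng.integers(0, max(1, stride - glen - 2 * margin)))
        tx_start = anchor + jitter
        tx_end = tx_start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        # exon blocks: first and last fixed to the gene ends, interior spread out
        bounds = np.linspace(tx_start, tx_end, n_exons + 1).astype(int)
        exon_starts, exon_ends = [], []
        for k in range(n_exons):
            lo, hi = int(bounds[k]), int(bounds[k + 1])
            elen = min(hi - lo, int(rng.integers(150, 400)))
            exon_starts.append(lo)
            exon_ends.append(lo + max(50, elen))
        symbol = f"gene{gi + 1}"
        gene = GeneModel(
            chrom, strand, tx_start, tx_end,
            tuple(exon_starts), tuple(exon_ends), symbol,
        )
        genes.append(gene)
        truth.tss[symbol] = (chrom, gene.tss, strand)
    return genes, truth


# ---------------------------------------------------------------------------
# Peak planting


def _sample_pwm_instance(
    pwm: PWM,
    rng: np.random.Generator,
    min_mss: float,
    forced: Mapping[int, str] | None = None,
) -> str:
    """Draw a sequence from the matrix frequencies, rejecting low-scoring draws.

    ``forced`` pins positions to fixed bases before scoring (used to plant
    instances whose core is the exact CCAAT pentamer).
    """
    from .pwm import score_window  # local import avoids cycle at module load

    for _ in range(1000):
        codes = [int(rng.choice(4, p=row)) for row in pwm.freqs]
        if forced:
            for i, base in forced.items():
                codes[i] = "ACGT".index(base)
        inst = "".join("ACGT"[c] for c in codes)
        if score_window(pwm, inst) >= min_mss:
            return inst
    raise RuntimeError(
        f"could not sample an instance of {pwm.id} with MSS >= {min_mss}"
    )


def _sample_nfy_instance(nfy: PWM, rng: np.random.Generator, min_mss: float) -> str:
    """NF-Y matrix instance whose core is forced to the exact CCAAT pentamer."""
    forced = {NFY_CORE_OFFSET + i: b for i, b in enumerate("CCAAT")}
    return _sample_pwm_instance(nfy, rng, min_mss, forced)


def _sample_width(spec: PlantingSpec, rng: np.random.Generator) -> int:
    w = int(round(rng.normal(spec.peak_width_mean, spec.peak_width_sd)))
    return max(spec.min_peak_width, w)


class _MutableGenome:
    def __init__(self, genome: Mapping[str, str]):
        self.seqs = {name: bytearray(seq, "ascii") for name, seq in genome.items()}

    def plant(self, chrom: str, pos: int, motif: str) -> None:
        self.seqs[chrom][pos : pos + len(motif)] = motif.encode("ascii")

    def freeze(self) -> dict[str, str]:
        return {name: bs.decode("ascii") for name, bs in self.seqs.items()}


def _free_spans(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    clearance: int = 2000,
) -> list[tuple[str, int, int]]:
    """Intergenic spans at least ``clearance`` bp away from any gene body."""
    spans: list[tuple[str, int, int]] = []
    for chrom in genome:
        bodies = sorted(
            (g.tx_start, g.tx_end) for g in genes if g.chrom == chrom
        )
        prev = 0
        for s, e in bodies:
            lo, hi = prev + clearance, s - clearance
            if hi - lo >= 200:
                spans.append((chrom, lo, hi))
            prev = max(prev, e)
        lo, hi = prev + clearance, len(genome[chrom]) - clearance
        if hi - lo >= 200:
            spans.append((chrom, lo, hi))
    return spans


class _SpanAllocator:
    """Sequentially allocate non-overlapping windows from free spans."""

    def __init__(self, spans: Sequence[tuple[str, int, int]], rng: np.random.Generator):
        order = rng.permutation(len(spans))
        self._spans = [spans[i] for i in order]
        self._idx = 0
        self._cursor = self._spans[0][1] if spans else 0

    def take(self, width: int, gap: int = 50) -> tuple[str, int, int]:
        while self._idx < len(self._spans):
            chrom, lo, hi = self._spans[self._idx]
            start = max(self._cursor, lo)
            if start + width <= hi:
                self._cursor = start + width + gap
                return chrom, start, start + width
            self._idx += 1
            if self._idx < len(self._spans):
                self._cursor = self._spans[self._idx][1]
        raise ValueError(
            f"peak placement exhausted free spans (requested width {width})"
        )


def _plant_peak(
    mg: _MutableGenome,
    spec: PlantingSpec,
    set_name: str,
    peak_name: str,
    chrom: str,
    start: int,
    end: int,
    rng: np.random.Generator,
    ap1: PWM,
) -> TruthRecord:
    width = end - start
    u = rng.random()
    motif: str | None = None
    strand: str | None = None
    positions: tuple[int, ...] = ()
    delta: int | None = None
    if u < spec.ap1_prevalence:
        motif = "ap1"
        inst = _sample_pwm_instance(ap1, rng, spec.min_planted_mss)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = inst if strand == "+" else reverse_complement(inst)
        pos = start + int(rng.integers(5, width - len(inst) - 5))
        mg.plant(chrom, pos, planted)
        positions = (pos,)
    elif u < spec.ap1_prevalence + spec.ccaat_prevalence:
        strand = "+" if rng.random() < 0.5 else "-"
        nfy = nfy_pwm()
        L = len(nfy)

        def plant_box(box_pos: int) -> None:
            # full flanked instance; its exact-CCAAT core starts at box_pos
            inst = _sample_nfy_instance(nfy, rng, spec.min_planted_mss)
            planted = inst if strand == "+" else reverse_complement(inst)
            # on either strand the core (CCAAT or ATTGG) sits at the same offset
            mg.plant(chrom, box_pos - NFY_CORE_OFFSET, planted)

        if spec.dimer_spacing and rng.random() < spec.dimer_fraction:
            motif = "ccaat_dimer"
            deltas = sorted(spec.dimer_spacing)
            weights = np.array([spec.dimer_spacing[d] for d in deltas], dtype=float)
            delta = int(rng.choice(deltas, p=weights / weights.sum()))
            span = delta + L  # first instance start to last instance end
            if width < span + 10:
                raise ValueError(
                    f"peak width {width} too small for dimer spacing {delta}"
                )
            pos = start + NFY_CORE_OFFSET + int(
                rng.integers(5, width - span - 5)
            )
            plant_box(pos)
            plant_box(pos + delta)
            positions = (pos, pos + delta)
        else:
            motif = "ccaat_single"
            pos = start + NFY_CORE_OFFSET + int(rng.integers(5, width - L - 10))
            plant_box(pos)
            positions = (pos,)
    return TruthRecord(
        set_name, peak_name, chrom, start, end, motif, strand, positions, delta
    )


def generate_peak_sets(
    genome: Mapping[str, str],
    annotation: Sequence[GeneModel],
    specs: Mapping[str, PlantingSpec],
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, list[GenomicInterval]], SyntheticTruth]:
    """Plant motif content per spec and return (genome, peak sets, truth).

    Proximal specs place one peak inside the upstream-window/TSS neighborhood
    of distinct genes; distal specs place peaks in intergenic space with 2 kb
    clearance from gene bodies.  The returned genome carries the planted
    instances; the input mapping is not modified.
    """
    seqs = np.random.SeedSequence(seed).spawn(len(specs) + 2)
    mg = _MutableGenome(genome)
    truth = SyntheticTruth()
    ap1 = ap1_pwm()
    peak_sets: dict[str, list[GenomicInterval]] = {}
    spans = _free_spans(genome, annotation)
    # one shared allocator and gene queue keep peak sets non-overlapping, so
    # planted content never leaks between sets (a DNase-like background set
    # stays free of planted motifs); co-localizing sets are built explicitly
    # by the callers that need them
    shared_rng = np.random.default_rng(seqs[-1])
    alloc = _SpanAllocator(spans, shared_rng)
    gene_queue = list(shared_rng.permutation(len(annotation)))
    for (set_name, spec), seedseq in zip(specs.items(), seqs):
        rng = np.random.default_rng(seedseq)
        peaks: list[GenomicInterval] = []
        if spec.region == "proximal":
            genes = [g for g in annotation]
            if spec.n_peaks > len(gene_queue):
                raise ValueError(
                    f"set {set_name}: {spec.n_peaks} proximal peaks exceed "
                    f"{len(gene_queue)} unused genes"
                )
            order = [gene_queue.pop() for _ in range(spec.n_peaks)]
            for k, gidx in enumerate(order):
                g = genes[gidx]
                width = min(_sample_width(spec, rng), 900)
                if g.strand == "+":
                    start = g.tss - 1000 + int(rng.integers(0, 1000 - width))
                else:
                    start = g.tss + int(rng.integers(0, 1000 - width))
                name = f"{set_name}_{k + 1}"
                iv = GenomicInterval(g.chrom, start, start + width, name)
                peaks.append(iv)
                truth.records.append(
                    _plant_peak(mg, spec, set_name, name, g.chrom, start, start + width, rng, ap1)
                )
        else:
            for k in range(spec.n_peaks):
                width = _sample_width(spec, rng)
                chrom, start, end = alloc.take(width)
                name = f"{set_name}_{k + 1}"
                peaks.append(GenomicInterval(chrom, start, end, name))
                truth.records.append(
                    _plant_peak(mg, spec, set_name, name, chrom, start, end, rng, ap1)
                )
        peak_sets[set_name] = peaks
    return mg.freeze(), peak_sets, truth


# ---------------------------------------------------------------------------
# High-level study generators


def simulate_study(
    seed: int = 0,
    n_genes: int = 50,
    n_distal: int = 300,
    n_proximal: int = 40,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate the four-set stand-in study: factor peaks, background, co-activator.

    Produces an AP-1-factor-like distal set (85% planted AP-1 prevalence, the
    proportion seen in enhancer-like ChIP sets), a CCAAT-factor-like set with
    a proximal dimer-bearing portion and a distal LTR-like portion, a
    DNase-like background set with no planted motifs, and a co-activator-like
    set built to overlap most factor peaks.  When ``out_dir`` is given, FASTA,
    BED12, narrowPeak and truth/parameter files are written there.
    """
    root = np.random.SeedSequence(seed)
    g_seed, a_seed, p_seed, x_seed = [int(s.generate_state(1)[0]) % (2**31) for s in root.spawn(4)]
    chrom_len = max(200_000, n_genes * 20_000 + 100_000, int(n_distal * 3.5 * 450))
    spec = GenomeSpec({"chr1": chrom_len}, gc_content=0.41, seed=g_seed)
    genome = generate_genome(spec)
    annotation, truth0 = generate_annotation(genome, n_genes=n_genes, seed=a_seed)
    specs = {
        "fos_like": PlantingSpec(
            n_peaks=n_distal, ap1_prevalence=0.90, region="distal"
        ),
        "nfyb_like_proximal": PlantingSpec(
            n_peaks=n_proximal, ccaat_prevalence=0.80, dimer_fraction=0.6,
            region="proximal",
        ),
        "nfyb_like_distal": PlantingSpec(
            n_peaks=n_distal, ccaat_prevalence=0.80, dimer_fraction=0.6,
            dimer_spacing=dict(LTR_SPACING), region="distal",
        ),
        "dhs_background": PlantingSpec(n_peaks=n_distal, region="distal"),
    }
    genome, peak_sets, truth = generate_peak_sets(genome, annotation, specs, seed=p_seed)
    truth.tss = truth0.tss

    # co-activator-like set: windows centered on a subset of factor peaks
    rng = np.random.default_rng(x_seed)
    p300: list[GenomicInterval] = []
    pool = [(iv, 0.87) for iv in peak_sets["fos_like"]] + [
        (iv, 0.56)
        for iv in peak_sets["nfyb_like_proximal"] + peak_sets["nfyb_like_distal"]
    ]
    k = 0
    for iv, prob in pool:
        if rng.random() < prob:
            k += 1
            shift = int(rng.integers(-100, 100))
            start = max(0, iv.start + shift)
            p300.append(
                GenomicInterval(iv.chrom, start, start + len(iv), f"p300_like_{k}")
            )
    peak_sets["p300_like"] = p300

    study = {
        "genome": genome,
        "annotation": annotation,
        "peak_sets": peak_sets,
        "truth": truth,
        "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_bed12(annotation, out / "genes.bed12")
        for name, peaks in peak_sets.items():
            write_bed(peaks, out / f"{name}.narrowPeak", narrowpeak=True)
        truth.write_tsv(out / "truth.tsv")
        params = {
            "seed": seed, "n_genes": n_genes, "n_distal": n_distal,
            "n_proximal": n_proximal, "chrom_lengths": {"chr1": chrom_len},
            "sets": {k: {kk: vv for kk, vv in asdict(v).items()} for k, v in specs.items()},
        }
        (out / "parameters.json").write_text(json.dumps(params, indent=2, default=str))
    return study


def simulate_motif_sets(
    seed: int = 0,
    n_per_set: int = 350,
    prevalence_pairs: Sequence[tuple[str, float, float]] = TABLE4_LIKE_PREVALENCES,
) -> tuple[dict[str, str], dict[str, list[GenomicInterval]], SyntheticTruth]:
    """Peak sets with per-set exclusive AP-1/CCAAT prevalences for the
    mutual-exclusivity experiment (defaults mirror the eight observed
    proximal/distal sets of the four cell lines)."""
    root = np.random.SeedSequence(seed)
    g_seed, p_seed = [int(s.generate_state(1)[0]) % (2**31) for s in root.spawn(2)]
    n_total = n_per_set * len(prevalence_pairs)
    chrom_len = max(200_000, int(n_total * 450))
    genome = generate_genome(GenomeSpec({"chrM1": chrom_len}, seed=g_seed))
    specs = {
        label: PlantingSpec(
            n_peaks=n_per_set,
            ap1_prevalence=ap1,
            ccaat_prevalence=ccaat,
            dimer_fraction=0.3,
            region="distal",
        )
        for label, ap1, ccaat in prevalence_pairs
    }
    return generate_peak_sets(genome, [], specs, seed=p_seed)


def simulate_ep_dataset(
    seed: int = 0,
    n_promoters: int = 150,
    n_per_group: int = 400,
    promoter_stride: int = 100_000,
    near_gap: tuple[int, int] = (1_000, 20_000),
    far_gap: tuple[int, int] = (30_000, 90_000),
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval]]:
    """Promoters plus two enhancer groups, group A constructed strictly nearer.

    Promoters sit every ``promoter_stride`` bp; each promoter gets one group-A
    enhancer at a gap drawn from ``near_gap`` and one group-B enhancer at a
    gap from ``far_gap`` (sides alternate by draw); surplus enhancers of
    either group are placed mid-stride.  No sequence is attached — distance
    analysis is purely interval arithmetic.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    promoters: list[GenomicInterval] = []
    group_a: list[GenomicInterval] = []
    group_b: list[GenomicInterval] = []
    width_p, width_e = 1000, 500
    chrom = "chrE1"
    for i in range(n_promoters):
        p_start = 40_000 + i * promoter_stride
        promoters.append(
            GenomicInterval(chrom, p_start, p_start + width_p, f"prom_{i + 1}")
        )
        for group, gaps, tag in ((group_a, near_gap, "a"), (group_b, far_gap, "b")):
            gap = int(rng.integers(gaps[0], gaps[1]))
            if rng.random() < 0.5 and p_start - gap - width_e > 0:
                start = p_start - gap - width_e
            else:
                start = p_start + width_p + gap
            group.append(
                GenomicInterval(chrom, start, start + width_e, f"enh_{tag}_{i + 1}")
            )
    # surplus enhancers mid-stride, far from every promoter
    k = n_promoters
    while len(group_a) < n_per_group or len(group_b) < n_per_group:
        k += 1
        mid = 40_000 + (k % n_promoters) * promoter_stride + promoter_stride // 2
        jitter = int(rng.integers(-5000, 5000))
        start = mid + jitter
        if len(group_a) < n_per_group:
            group_a.append(GenomicInterval(chrom, start, start + width_e, f"enh_a_{k}"))
        if len(group_b) < n_per_group:
            group_b.append(
                GenomicInterval(chrom, start + 7000, start + 7000 + width_e, f"enh_b_{k}")
            )
    return promoters, group_a, group_b
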