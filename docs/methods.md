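# Methods

This note records the models, conventions and numerical choices behind
`motifarch`, and what the synthetic-data experiments do and do not
demonstrate.

## Interval model and region classes

All coordinates are 0-based, half-open (BED convention), and overlap means at
least one shared base pair — no minimum-overlap fraction is applied anywhere.
Gene models are transcription units with exon blocks; the TSS is the 5' end
on the coding strand (`tx_start` for `+`, `tx_end` for `-`), and the first
exon is the 5'-most block.

Region classification is strand-aware: *proximal* intervals overlap the
union of the upstream window `[TSS − u, TSS)` (default `u` = 1000 bp) and
the first exon; *distal* intervals overlap neither that window nor any
transcription unit; everything else (gene-body-only overlap beyond the first
exon) is *excluded* and dropped from both sides of downstream comparisons.
Intervals on chromosomes absent from the annotation classify as distal with
a logged warning, so scaffolds do not abort a pipeline.

Co-localization statistics count *merged maximal blocks* of the pooled
interval sets: a block is shared when it contains at least one interval from
each source. Counting original peak records instead is available
(`partition_by_overlap(..., count="records")`) because either reading of
"unique genomic intervals" is defensible; merged blocks are the default.
In multi-sample union grouping, a block is assigned to the intersection
group whenever both factors occupy it, regardless of which sample each peak
came from; this keeps the three output groups disjoint and jointly covering
every input span (a same-sample-only rule would leave blocks carrying the
two factors from different samples unassignable).

## MATCH-style matrix similarity

A PWM is an L×4 count table; frequencies are
`f(i,b) = (count + pc) / (rowsum + 4·pc)` with pseudocount `pc = 0` by
default (an explicit opt-in, since curated matrix libraries ship counts that
are used as-is). The information vector is `I(i) = Σ_b f ln(4f)` with
`0·ln 0 := 0`; a window scores `(Current − Min)/(Max − Min)` where Current,
Max and Min are the information-weighted sums of the window's, the maximal
and the minimal per-position frequencies. Conventions:

- fully uniform matrices (Max = Min) score 1.0 everywhere and are flagged in
  logs;
- windows containing non-ACGT characters are skipped rather than scored 0,
  so assembly gaps do not create artificial negatives;
- minus-strand hits are reported at the forward-strand start of the window
  they cover;
- the core-similarity score uses the 5 consecutive positions with maximal
  summed information (ties to the smallest start) and is inert at the
  default `css_threshold = 0`.

## ROC / MCC benchmarking

Interval-level: a positive (ChIP-like) interval is a true positive at
threshold t when its best window score reaches t; a background (DNase-like,
pre-subtracted of ChIP overlap) interval reaching t is a false positive.
The threshold sweep uses every distinct observed best score within
[0.5, 1.0] plus the 0.5 floor — not a fixed grid — which makes the trapezoid
AUC exactly equal to the Mann-Whitney pair-counting statistic when all
scores lie above the floor, and hence reproducible to machine precision.
The curve is closed to (1, 1) by default so the AUC is a full-range area;
`close=False` gives the truncated variant. Intervals with no scorable window
count as −∞ (always FN/TN). MCC tie-breaks go to the stricter (higher)
threshold.

## Fisher statistics

The two-sided exact p sums hypergeometric point probabilities no larger than
the observed table's (the minimum-likelihood convention; delegated to
scipy, which implements exactly this). The reported odds ratio is the
conditional MLE: the ψ solving `E[a | margins, ψ] = a` under Fisher's
noncentral hypergeometric distribution, found by bisection on log ψ with the
pmf evaluated in log space; boundary tables return 0/∞ and zero-margin
tables have no estimate. This is the quantity R's `fisher.test` reports; it
shrinks toward 1 relative to the cross-product ratio `ad/bc`, which is also
returned. Note that R's root finder stops at a loose tolerance
(≈1e-4 on 1/ψ), so published values produced with R can differ from the
exact root in the third decimal (e.g. 32.622 vs 32.628); the bisection here
drives the score-equation residual below 1e-8.

The mutual-exclusivity summary plots, per interval set, the percentage of
intervals with an AP-1 match against the percentage with an NF-Y match and
reports Pearson r. Because the percentage convention is genuinely ambiguous,
three definitions are implemented — `inclusive` (motif present, double
occurrences counted on both axes; the default), `exclusive` (only-this-motif
counts), and `either_only` (denominator restricted to intervals with at
least one motif) — and on the same counts they give visibly different r (on
the published example tallies: −0.941, −0.914, −0.997).

## CCAAT architecture

CCAAT boxes are exact regular-expression matches of `CCAAT` (+) and `ATTGG`
(−) on the forward sequence, all overlapping occurrences reported. Repeat
configuration uses the priority direct-repeat (≥2 same-strand boxes) >
opposed pair (both strands, inverted and everted pooled) > single. Tandem
spacing is start-to-start (first C to first C) between *consecutive*
same-strand boxes: start-to-start is the convention under which the NF-Y
protein footprint — contacts from −7 (NF-YC side) to +17 (NF-YB side)
around the first C — yields a minimum spacing of 7 + 17 = 24 bp, and
consecutive-neighbor pairing avoids double-counting triplets, which would
blur the 10–11 bp helical-phasing structure of the spacing spectrum.
Spectrum peaks are local maxima of the count-vs-spacing profile above a
caller-chosen minimum count; reference spacings 24/31/41/51 bp are annotated
in reports.

## Enhancer-promoter distances

Distances here are edge-to-edge gaps (promoter start − enhancer end
upstream, enhancer start − promoter end downstream; 0 on overlap) —
deliberately a different convention from the CCAAT start-to-start spacing,
and both are named distinctly. Equidistant up/downstream ties resolve
upstream. The group comparison subsamples each enhancer group to a fixed
size per repetition (without replacement), records every promoter's nearest
distance to each subgroup, and pools across repetitions before a single
Mann-Whitney test; a per-repetition summary could be added but pooling is
the default. The test uses midranks with tie-corrected variance, a 0.5
continuity correction, and evaluates the two-sided normal tail in log space,
so extreme separations report a finite `log10_p` (the linear p is floored at
the smallest positive double). For samples of ≤8 the normal approximation
stays within ~10 % of exact enumeration.

## Synthetic data: what it emulates

The generator produces i.i.d. random genomes at a target GC content (default
0.41, the human genome-wide value), evenly strided non-overlapping
multi-exon genes on both strands, and peak sets of normally distributed
widths (mean 300 bp, SD 50 bp, floor 120 bp — typical point-source peak
calls). Planted content:

- AP-1 instances sampled from the bundled synthetic AP-1 matrix and
  rejected below an MSS floor of 0.95 ("high-affinity" sites);
- NF-Y instances sampled the same way with their core pinned to the literal
  CCAAT pentamer, so PWM detection and regex detection see the same planted
  object; dimers are two such instances at a start-to-start spacing drawn
  from a categorical distribution — promoter-like
  {24: .10, 31: .45, 41: .20, 52: .15, 63: .10} (dominant 31 bp mode with
  10–11 bp harmonics) or LTR-like {24: .55, 41: .45};
- a DNase-like background set with no planted instances (chance motif
  occurrences remain, intentionally, so ROC curves are nondegenerate).

Peak sets generated in one call are placed disjointly (shared allocator), so
planted content never leaks into the background; co-localizing sets (the
co-activator-like set, union-group inputs) are constructed explicitly from
factor peaks instead. The AP-1 planting prevalence of the factor-like distal
set is 0.90: with exclusive planting the interval-level AUC has ceiling
(1 + θ)/2, so θ must exceed 0.8 for any benchmark to exceed AUC 0.9, and
θ = 0.9 produces measured AP-1⁺ fractions near the ~85 % seen in real
enhancer-like ChIP sets once threshold losses are taken. The eight-set
mutual-exclusivity experiment uses per-set (AP-1, CCAAT) prevalence pairs
patterned on observed proximal/distal proportions across four cell lines.

Problem sizes are chosen for fast desk-scale runs: 300 peaks per distal set,
40 proximal peaks (bounded by the gene count), 500 peaks per set in the
exclusivity experiment, 150 promoters and 400 + 400 enhancers with a
20 × 300 resampling plan in the distance experiment. One master seed fans
out to per-component `SeedSequence` streams, so outputs are byte-reproducible
and adding a stage never perturbs earlier ones.

What passing synthetic tests shows — and does not. The generator's i.i.d.
background has no repeats, no GC isochores, no nucleosome structure and no
correlated peak co-occurrence; planted motifs are clean single instances.
Recovery results therefore validate the *machinery* (scoring, sweeping,
counting, testing) and its calibration on known ground truth, not the
biological effect sizes achievable on real genomes, where chance motif
density, repeat-derived CCAAT clusters (LTR12) and cell-type heterogeneity
compress AUCs and correlations well below the synthetic values.

## Known limitations

- No p-value calibration of MSS scores, dinucleotide background models, or
  de novo motif discovery; matrices must be supplied (or the bundled
  synthetic examples used).
- Fisher p-values are reported raw, without multiple-testing correction
  across sets.
- The union-set analysis does not lift peaks between assemblies and performs
  no summit-based re-centering.
- The enhancer-promoter analysis pairs by linear proximity only; no
  chromatin-contact information is used.
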