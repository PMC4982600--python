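# motifarch

Motif architecture analysis of transcription-factor-bound regulatory regions.

ChIP-seq peak sets for the AP-1 component c-Fos show a striking split: distal
(enhancer-like) peaks tend to carry the classical AP-1 consensus TGA(C/G)TCA,
while proximal (promoter-like) peaks are instead dominated by CCAAT boxes —
the binding element of the heterotrimeric factor NF-Y — and the two motifs
occur in a mutually exclusive fashion. `motifarch` packages the full analysis
workflow behind that kind of observation so it can be run on any
narrowPeak/BED + FASTA + gene-model input, and ships a synthetic-data
generator that plants known motif architecture so every stage can be
validated end to end without external downloads.

The toolkit covers, as importable modules:

- **`motifarch.intervals`** — 0-based half-open genomic intervals,
  narrowPeak/BED3/BED6/BED12 I/O, overlap algebra (merge, subtract,
  three-way co-localization partitions, multi-sample union grouping), and
  TSS-relative classification: an interval is *proximal* if it overlaps the
  strand-aware window `[TSS − 1000, TSS)` or the first exon of a gene,
  *distal* if it overlaps neither that window nor any transcription unit,
  and *excluded* otherwise.
- **`motifarch.pwm`** — TRANSFAC-format matrix parsing and MATCH-style
  scanning. Each matrix position carries an information weight
  `I(i) = Σ_b f(i,b) ln(4 f(i,b))`, and a window scores
  `MSS = (Current − Min)/(Max − Min)` with
  `Current = Σ_i I(i) f(i, b_i)`, so the consensus scores exactly 1 and the
  anti-consensus exactly 0. Both strands are scanned; core-similarity (CSS)
  filtering over the 5 most informative consecutive positions is available.
- **`motifarch.roc`** — interval-level benchmarking: an interval is a hit
  when it contains at least one window at or above the threshold; sweeping
  all observed best scores from 1.0 down to 0.5 yields a ROC curve
  (TPR = TP/(TP+FN) vs FPR = FP/(FP+TN)), trapezoid AUC, and the
  MCC-optimal matrix-similarity threshold, where
  `MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))`.
- **`motifarch.cooccurrence`** — AP-1/NF-Y presence classes, 2×2 tables with
  row odds, Fisher's exact test with the *conditional maximum-likelihood*
  odds ratio (the ψ solving `E[a | margins, ψ] = a` under the noncentral
  hypergeometric law — the estimate R's `fisher.test` reports), and the
  mutual-exclusivity scatter: per-set %AP-1 vs %NF-Y with Pearson r.
- **`motifarch.ccaat`** — CCAAT boxes as exact `CCAAT`/`ATTGG` matches,
  repeat-configuration classes (none / single / inverted–everted pair /
  direct repeat), start-to-start tandem spacing spectra whose peaks at
  31/41/52... bp reveal helical phasing, and the NF-Y footprint arithmetic:
  contacts spanning −7 to +17 around the first C force a minimum
  start-to-start spacing of 24 bp between adjacent NF-Y sites.
- **`motifarch.epdistance`** — nearest-enhancer edge-to-edge gaps per
  promoter, repeated equal-size subsampling of two enhancer groups, and a
  tie-corrected Mann-Whitney test evaluated in log space so that p-values
  far below double-precision underflow still report a finite `log10_p`.
- **`motifarch.simulate`** — genomes, gene annotations and peak sets with
  planted AP-1 instances, CCAAT singletons and CCAAT direct repeats at
  controlled spacings, plus a serialized ground-truth table.

Bundled synthetic AP-1/NF-Y example matrices (`motifarch.synthetic_matrices`)
are constructed from the published consensus motifs and stand in for
proprietary matrix-library content.

## Worked example

```python
from motifarch.simulate import simulate_study
from motifarch.roc import interval_best_scores, roc_curve, optimize_mcc
from motifarch.synthetic_matrices import ap1_pwm
from motifarch.ccaat import distance_spectrum
from motifarch.cooccurrence import ContingencyTable, fisher_exact

study = simulate_study(seed=1, out_dir="demo_study")
genome, sets = study["genome"], study["peak_sets"]

ap1 = ap1_pwm()
pos = interval_best_scores(ap1, sets["fos_like"], genome)
neg = interval_best_scores(ap1, sets["dhs_background"], genome)
print(f"AP-1 matrix AUC (factor peaks vs background): {roc_curve(pos, neg).auc:.3f}")
scan = optimize_mcc(pos, neg)
print(f"MCC-optimal MSS threshold: {scan.optimal_threshold:.3f} (MCC = {scan.optimal_mcc:.2f})")

seqs = [genome[p.chrom][p.start:p.end] for p in sets["nfyb_like_distal"]]
hist = distance_spectrum(seqs)
print(f"CCAAT tandem spacing mode in the LTR-like set: {hist.mode} bp ({hist.total} dimer pairs)")

res = fisher_exact(ContingencyTable(203, 198, 53, 1692))
print(f"CCAAT enrichment, proximal vs distal: OR = {res.or_mle:.2f}, p = {res.p_two_sided:.3g}")
```

prints

```
AP-1 matrix AUC (factor peaks vs background): 0.944
MCC-optimal MSS threshold: 0.951 (MCC = 0.91)
CCAAT tandem spacing mode in the LTR-like set: 24 bp (233 dimer pairs)
CCAAT enrichment, proximal vs distal: OR = 32.63, p = 1.18e-118
```

Reading the output: the AP-1 matrix separates the AP-1-planted factor peaks
from open-chromatin background almost perfectly (AUC 0.944, against 0.5 for
an unrelated matrix), and the MCC sweep recovers a detection threshold at the
planting floor of the generator. The LTR-like CCAAT set shows the 24 bp
spacing mode — two NF-Y footprints packed immediately adjacent — whereas the
promoter-like set peaks at 31 bp (one extra helical turn). The 2×2 example is
a motif-presence table (CCAAT+/− in proximal vs distal peaks): the
conditional-MLE odds ratio of ≈ 32.6 quantifies the strong promoter-side
CCAAT enrichment.

The same steps are available from the shell via the `motifarch` console
script (`simulate`, `classify`, `scan`, `roc`, `cooccur`, `ccaat`, `epdist`,
`report` subcommands); each writes tab-separated outputs plus the effective
configuration into its `--out-dir`.

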