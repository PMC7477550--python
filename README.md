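# rhythmix

Circadian "reprogramming" analysis for multi-condition expression time
courses: which genes oscillate, how the oscillating set changes between
conditions, and which transcription factors plausibly drive the genes
that start cycling only under treatment.

The package is aimed at transcriptomics analyses of the common circadian
design — bulk RNA-seq (FPKM-like values) sampled every 4 h across a day
(ZT 3, 7, 11, 15, 19, 23) with ~3 replicates per timepoint, under two or
more conditions (e.g. 2 genotypes x 2 treatments). Everything is usable
from Python; a thin `rhythmix` CLI wraps the same functions, and a
synthetic-data generator with known ground truth makes every stage
testable without any download.

## What it computes

**Rhythm detection.** Each gene's series `x` is compared against cosine
reference patterns `ref(t) = cos(2π(t − t₀ − L)/P)` over a grid of
periods `P ∈ {20, 24, 28}` h and lags `L` at the 4 h sampling resolution
(18 combinations). The statistic is Kendall's

&nbsp;&nbsp;&nbsp;&nbsp;`S = Σ_{i<j} sign(x_i − x_j) · sign(ref_i − ref_j)`

with replicates entering as exact ties in the reference. The p-value is
**exact**: the null distribution of S conditional on the tie patterns of
both sequences is computed by a Harding-style polynomial-convolution
dynamic program (integer counts, no normal approximation), the minimum p
over the grid is Bonferroni-multiplied by 18, and a gene is called
rhythmic when the adjusted p < 0.01. Reported per gene: adjusted p,
period, lag, peak phase in ZT hours, tau, and a cosinor amplitude (half
peak-to-trough of the least-squares cosine fit at the selected
period/phase).

**Preprocessing.** Dixon's Q test (n = 3..7, one-sided 95% critical
values, at most one replicate removed per gene × timepoint) prunes
replicate outliers; genes whose values stay below 1 (FPKM-like units) in
both compared conditions leave the analysis, while every gene with any
positive value stays in the enrichment background.

**Condition comparison.** For a condition pair (a, b): the Venn
partition into a-only / common / de-novo (b-only) oscillators with
percentages of the combined union; phase histograms (radar-plot data);
amplitude ratios `A_b/A_a` of common oscillators classed
higher/lower/equal; and phase-sorted, row z-scored heatmap matrices.

**TFBS enrichment.** A TF's binding sites (filtered at BBLS > 1 and
site FDR < 0.25; TFs with > 50000 filtered sites excluded as degenerate)
mark genes whose strand-aware promoter window (−10000/+2000 bp of the
TSS) they overlap. A one-sided Fisher exact test compares the rhythmic
set against the rest of the background, TFs are ranked by −log₁₀ p, and
a meta-analysis across conditions labels TFs significant in exactly one
condition as condition-exclusive. Target-gene sets intersect motif
evidence in a narrower −3000/+1000 window with ChIP peaks. A generic
GMT gene-set enrichment with BH q-values is included.

## Worked example

`python examples/03_tfbs_enrichment.py` (1000 synthetic genes, seed 3)
prints:

```
TFs ranked by -log10 p in the 104-gene de-novo set:
  PPARG      k= 18/104  -log10 p =  10.82
  DECOY14    k= 25/104  -log10 p =   1.33
  DECOY17    k= 21/104  -log10 p =   0.92
  DECOY05    k= 20/104  -log10 p =   0.89
  DECOY03    k= 22/104  -log10 p =   0.72

meta-analysis: PPARG is exclusive to: wt_coc

PPARG target set (motif + peak, -3000/+1000): 27 genes, 27 of them planted targets
```

104 genes became rhythmic only under treatment (the de-novo set); 18 of
them carry a quality-filtered PPARG site in their promoter window versus
a much lower background rate, giving −log₁₀ p ≈ 10.8 — far above every
decoy TF — and the meta-analysis over all four conditions flags PPARG as
exclusive to the treated wild-type condition, matching the planted
ground truth (sites seeded into de-novo promoters at rate 0.5 vs 0.05
elsewhere). The other examples cover rhythm detection
(`01_detect_rhythms.py`), set comparison (`02_compare_conditions.py`)
and the end-to-end pipeline with its checksummed manifest
(`04_full_pipeline.py`).

The same stages run from a shell:

```sh
rhythmix simulate --n-genes 500 --seed 1 --out-dir data/
rhythmix rhythm --in data/expression_wt_coc.tsv --out rhythm_coc.tsv
rhythmix run --out-dir run1 --seed 1          # full pipeline
```

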