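# Methods

## Rhythm detection

### Model and statistic

A gene's expression series over one day, `x_{t,r}` at timepoints `t`
(default ZT 3, 7, 11, 15, 19, 23) with replicates `r` (default 3), is
tested for monotone association with cosine reference patterns

    ref(t) = cos(2π (t − t₀ − L) / P),   t₀ = first sampling time,

so the reference peaks at `t₀ + L`. The grid holds every period `P` that
is an integer multiple of the sampling interval inside the 20–28 h
window (for 4 h sampling: 20, 24, 28 h) and every lag `L` that is a
multiple of the sampling interval in `[0, P)` — 5 + 6 + 7 = 18
combinations. A half-interval lag grid is available as an option but off
by default. The statistic per combination is Kendall's
`S = Σ_{i<j} sign(x_i − x_j)·sign(ref_i − ref_j)` over all sample pairs;
replicates at one timepoint are exact ties in the reference and tied
pairs (in either sequence) contribute zero. Being rank-based, every
result is invariant under strictly monotone transforms of the data, so
whether FPKMs are log-transformed upstream is immaterial.

### Exact conditional null

The null distribution of S conditions on the tie patterns of **both**
sequences: the multiset of x-values is placed uniformly at random over
the sample positions. The distribution is built exactly by a
polynomial-convolution dynamic program: x tie groups are inserted in
ascending value order; placing `c_i` items of a group into reference
tie-group `i` adds `c_i·(n_below − n_above)` to S (counts of previously
placed items in lower/higher reference groups) with multiplicity
`Π_i C(capacity_i, c_i)`. Counts are integers; for n ≤ 18 they stay
below 2⁶² so int64 arithmetic is exact. The two-sided p is
`P(|S| ≥ |S_obs|)`. Distributions are cached by tie-pattern pair, so a
matrix scan performs the DP a handful of times regardless of gene count.
The test suite checks the DP against exhaustive permutation enumeration.

The minimum p over the grid is Bonferroni-adjusted by the number of
combinations (18 by default; configurable to match other conventions,
since published JTK builds differ in how lag hypotheses are grouped),
capped at 1, and compared strictly against the 0.01 cutoff.

### Phase, antiphase, amplitude

The selected combination is the argmin of p, ties broken by smaller
period then smaller lag; the peak phase is `(t₀ + L) mod 24` ZT hours.
Because the two-sided test gives a reference and its negation identical
p, a selection with `S < 0` is folded to `L + P/2` with S negated — for
24 h references that antiphase lag is itself a grid point, but for 20
and 28 h periods it is not, and without the fold such selections would
report peaks ~12 h from the true peak. `tau = S / max|S|` with the
maximum taken over the conditional null's support.

Amplitude is the absolute cosine coefficient of an ordinary
least-squares cosinor fit at the selected period and phase on the
non-missing samples (half the peak-to-trough excursion, in the data's
units). This differs from the Hodges–Lehmann-type estimator some JTK
releases use; amplitudes here feed only the ratio taxonomy, which is
insensitive to a common choice of estimator.

### Degenerate inputs

All-missing or constant-after-masking series report adjusted p = 1,
tau = 0 and amplitude 0 (not an error); series with fewer than two
usable values at the statistic level raise.

### Period identifiability

Six timepoints at 4 h resolution cannot pin the period sharply. A
perfect 24 h cosine with tied replicates induces a ranking also fully
compatible with the 28 h reference, whose conditional null can assign it
a strictly smaller exact p; with realistic noise (untied data) the 24 h
reference wins for oscillators peaking near a sampled timepoint (~87%
in simulations) while off-grid phases split between 20/24/28. The
synthetic generator plants 24 h periods for exactly this reason, and
aggregate checks treat "period recovered" as the modal selected period.

## Preprocessing

Dixon's Q per gene × timepoint on the replicate values: the suspect is
the extreme with the larger gap to its neighbour, `Q = gap / range`,
flagged when Q exceeds the Dean–Dixon r10 one-sided 95% critical value
(0.941, 0.765, 0.642, 0.560, 0.507 for n = 3..7). Applying a one-sided
critical value to the more extreme tail makes the effective two-sided
level ~10%, so on clean data roughly a tenth of gene × timepoint cells
lose one replicate — the cost of a 3-replicate design; the test runs on
raw values (at n = 3 the choice between raw and log is minor, and it is
fixed here). At most one replicate is removed per cell, and cells with
fewer than three remaining replicates are skipped, which also makes
pruning idempotent. Zero range returns no outlier.

"Consistently low" expression means every non-missing value in **both**
compared conditions is below the threshold (default 1, FPKM-like units);
a mean-based variant is a config switch. The enrichment background keeps
every gene with any positive value anywhere — the analysis set is always
a subset of the background.

## Synthetic data

The generator emulates the target study design: 4 conditions (2
genotypes × 2 treatments), 6 timepoints × 3 replicates,

    value(g, c, t, r) = μ_g · (1 + a·cos(2π(t − φ)/P)) · exp(ε),
    ε ~ N(0, σ²) iid,   μ_g ~ LogNormal(3, 1),

with `a = 0` for non-oscillators. Noise is multiplicative because
FPKM-scale dispersion grows with the mean and positivity is preserved;
σ defaults to 0.1. The default plan per 2000 genes: 10% oscillate only
in the control wild type, 5% in both wild-type conditions (treated
amplitude rescaled by a LogNormal(0, 0.4) factor so the amplitude
taxonomy has all three classes), 10% de novo under treatment with
phases N(ZT7, 1.5 h) wrapped — mirroring a treatment-induced phase
cluster — and smaller (2.5%) analogous blocks in the knockout;
amplitudes are Uniform(0.3, 0.8) and the period is fixed at 24 h
(see identifiability above). Outliers: with probability 0.02 per
gene × timepoint one replicate is multiplied by 8.

The motif layer gives each gene a 20 kb territory on one synthetic
chromosome (TSS mid-territory, alternating strands). The focal TF
(named PPARG) gets a site uniformly inside the −3000/+1000 promoter
window of each de-novo gene with probability 0.5 and of every other
gene with probability 0.05; genes that actually received a site are the
ground-truth targets. Twenty decoy TFs get one site per territory on
average, uniformly. All sites draw `bbls ~ Exp(mean 2)` and
`fdr ~ U(0, 0.5)`, so roughly 30% survive the quality filters —
enrichment recovery is tested under realistic site attrition. Peaks
cover focal target sites with probability 0.9. All randomness flows
from one root seed through named child streams; outputs are
bit-reproducible.

What the generator does **not** emulate: count-level noise
(negative-binomial mean–variance), batch effects, correlated genes,
non-sinusoidal waveforms, overlapping gene territories, or strandless
motif tables mapping to several genes. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated model, not
performance on any real dataset.

## Enrichment

Promoter windows are strand-aware: for a + strand gene the window is
`[tss − up, tss + down)`; for a − strand gene upstream extends to larger
coordinates, `[tss − down + 1, tss + up + 1)`, covering the same offsets
along the direction of transcription. All intervals are 0-based
half-open; a site qualifies with ≥ 1 bp overlap. Site filters are
strict inequalities exactly as stated (BBLS > 1, FDR < 0.25, excluded
when filtered site count > 50000).

The 2×2 table is {in set} × {has ≥ 1 filtered site in window} with the
complement margin `background ∖ set` — disjoint cells are the only
construction giving a valid exact test. Gene-level presence (not site
counts) is tested, the test is one-sided for enrichment, and TFs are
ranked by −log₁₀ p without multiple-testing correction across TFs (BH
is available in the generic gene-set module). A TF is
condition-exclusive when `p ≤ α_tf` (default 0.01) in exactly one
condition, excluded/degenerate TFs counting as non-significant; the
exclusivity threshold is a design choice, and a top-k-by-rank rule can
be substituted via the records themselves.

Target sets intersect motif presence in the −3000/+1000 window with
ChIP-peak overlap of the same window ("combination" read as
intersection; union via `require_peak=False`).

## Pipeline

Conditions are analysed pairwise (control vs treated per genotype, by
default) with shared preprocessing; per-condition rhythmic sets feed the
enrichment meta-analysis. Every output file is sha256-checksummed into a
manifest; identical config + seed reproduces identical checksums. Sizes
in the test suite and acceptance script (2000-gene studies, 200
enumeration patterns, 1000 oracle tables) are the package's default
desk-scale study; the full published gene lists additionally require
the deposited RNA-seq and MotifMap/ChIP resources, which enter through
the same TSV/BED/GMT readers.

## Known limitations

* Exact p-values require n ≲ 30 samples per series (DP cost grows with
  the product of tie-group capacities); the intended designs (6 × 3)
  are far inside this.
* The amplitude estimator differs from JTK's native one (documented
  above); absolute amplitudes should not be compared across estimators.
* The Dixon table covers n = 3..7 replicates.
* No differential-rhythmicity statistics (set operations only), no
  normalisation, and no read-level processing — inputs are expression
  matrices.
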