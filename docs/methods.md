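# Methods

## Enhancer classification model

Classification works on a fixed 200 bp bucket grid per chromosome (the last
bucket of a chromosome may be shorter). Mark presence is binary per bucket:
a bucket counts as covered by a mark if any peak of that mark overlaps it by
at least 1 bp. This is deliberately the simplest deterministic overlap rule;
no minimum overlap fraction is imposed, because peak calls are already
segment-level evidence and fractional thresholds would introduce an
arbitrary parameter. A hidden-Markov chromatin segmentation is *not* fitted:
the KEE/non-KEE definition is a pure recombination of peak presence
(H3K4me1 ∧ H3K27ac ∧ H3K79me2/3 vs H3K4me1 ∧ H3K27ac ∧ ¬H3K79me2/3), so the
classifier consumes peak calls directly.

Merging uses a strict `gap < 1000 bp` rule on the bp gap between enhancer
buckets, so a 999 bp gap merges and a 1000 bp gap does not. The merged call
is a KEE if any constituent bucket is a KEE bucket — i.e. KEE evidence takes
precedence over non-KEE evidence within one element, mirroring the gene
labelling rule (a gene with both KEE and non-KEE assignments is a KEE gene).

Nearest-gene assignment measures edge-to-edge distance to gene *bodies*
(distance 0 for intragenic enhancers, which therefore always map to their
host gene); a TSS-distance mode exists behind a flag. Ties break to the
smaller start coordinate, then lexicographic gene id, for reproducibility.
Genes are flagged `h3k79_marked` by gene-body peak overlap only — a peak
ending 1 bp upstream of the body does not count. An optional
promoter-exclusion filter (H3K4me3 overlap or TSS ± 2 kb) is provided but
off by default: the classification rule names only the three marks.

## ChIP-rx normalization

The spike-in factor is the input-corrected spike ratio
`(s_input/t_input) / (s_ip/t_ip)`. This form is invariant to independent
depth rescaling of IP and input libraries, strictly decreasing in the IP
spike share, and equals 1 when IP and input have the same spike:target
composition. The exact formula used by the original ChIP-rx pipelines is
not uniquely fixed in the literature; this input-corrected form is the
standard construction and is the package's documented interpretation. The
counting unit is post-duplicate-removal mapped reads supplied as a table;
the package never computes counts from alignments.

## Differential Capture-C test

*Normalization.* Each replicate × condition column is scaled to reads per
100 000 cis-reported reads. The constant is arbitrary (it cancels in the
rank test) but keeps differential-track units interpretable. Totals default
to column sums when no explicit cis totals are supplied.

*Filtering.* Retained peaks must be cis to the probe, fully inside the
probe's interaction domain, and more than `exclusion_radius` (default
10 kb) from the probe hybridization site, edge to edge — proximity-ligation
signal near the viewpoint is uninformative.

*Pairing.* The test unit is (fragment, replicate index): every fragment
overlapping the peak contributes one pair per replicate, control replicate
*i* against treated replicate *i*. Index pairing is the only deterministic
choice when replicates are otherwise exchangeable; fragment-wise pooling
across replicates maximizes the number of pairs per peak, which matters
because single fragments are noisy.

*Signed-rank conventions.* Zero differences are dropped (reduced-sample
convention) and tied absolute differences receive midranks. Sparse fragment
counts make both cases common, so they are first-class: the exact p-value
is computed from the full permutation distribution of the positive-rank sum
via convolution over doubled (integer) midranks — mathematically identical
to enumerating all 2^n sign assignments, and exact in double precision
because all probabilities are dyadic rationals for n ≤ 25. Above 25 pairs a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used; 2^25 is the practical enumeration ceiling and the
threshold is configurable. The two-sided p is `2·min(P(W ≤ w), P(W ≥ w))`
capped at 1. All pairs zero gives W = 0, p = 1 (no evidence).

*Multiple testing.* Holm–Bonferroni step-down within the retained-peak
family of one probe: each captured promoter is its own family, matching how
per-gene interaction panels are read.

*Differential track.* Per fragment, the mean over replicates of the
normalized treated − control difference, smoothed by a centered sliding
mean over an odd number of fragments (default 5) that truncates at the
ends. With window 1 the track's signed sum equals the difference of the
normalized library sums — a conservation identity the tests check.

*Peak derivation.* The study drew interaction-domain peaks by eye, which
has no algorithmic description, so supplying peaks as a BED is the primary
route; a fallback caller thresholds the smoothed control mean at a
quantile (default 0.9) and keeps runs of ≥ 3 fragments.

## Integration statistics

Fisher's exact test is computed in exact rational arithmetic (`Fraction`)
over the hypergeometric support, summing probabilities of tables no more
probable than the observed one. A `(1 + 1e-7)` relative gate is applied on
that comparison — the same convention as the standard R and scipy
implementations — so borderline equal-probability tables are included
despite floating representation. The odds ratio is the sample OR
`ad/bc` with `inf`/`nan` for degenerate margins. Rank-sum p-values are
exact (distribution built by dynamic programming over midranks) when the
smaller group has ≤ 12 members and the combined sample ≤ 60; the DP cost
grows as N²·n₁, so beyond that the tie-corrected normal approximation is
used. The DE status rule is FDR < 0.05 plus the sign of log2FC with no
fold-change floor.

For the mark-correlation analysis, per-enhancer signal is the sum of
overlapped track-bin values with partial bins pro-rated by overlap
fraction, and the default transform is log2(x+1) — the standard variance
stabilization for read-count scatter; a raw mode exists. The class-level
mean log2FC comparison reports per-class means with significance from the
collapsed down-vs-not Fisher test (a Fisher test cannot be applied to a
mean directly).

ATAC peaks are assigned to exactly one enhancer-class bucket with KEE
precedence (KEE if overlapping any KEE, else non-KEE if overlapping any
non-KEE, else neither), and a decreased peak's gene is its containing
enhancer's assigned gene, falling back to nearest gene when gene models
are supplied.

Metaprofiles rescale each interval body to a fixed number of bins by
linear interpolation of the per-track-bin signal and add fixed-bp flank
windows; intervals shorter than one track bin are skipped and counted.

## Synthetic data: what it emulates and what it does not

The generator plants non-overlapping genes, then KEE and non-KEE enhancers
snapped to the 200 bp grid with ≥ 1.2 kb separation (above the 1 kb merge
gap, so distinct planted elements never fuse). Element lengths are
log-normal around medians of 1.0 kb (KEE) and 0.8 kb (non-KEE); 70% are
intragenic by default. Peaks are emitted *exactly* at true elements:
H3K4me1 + H3K27ac everywhere, H3K79me2 at KEEs, H3K79me3 copying me2 with
probability 0.97 (the me2/me3 concordance dial). Additional H3K79 gene-body
blocks cover a random 60% of genes — carved around any hosted non-KEE
element with a one-bucket margin — so gene-body marking is decoupled from
enhancer marking. Because peaks are noise-free, classifier recovery is
exact by construction; real peak calls carry boundary noise the generator
does not model, so passing recovery tests validate the *logic*, not
robustness to caller error.

Signal tracks give each enhancer a latent strength
`L = exp(σz − σ²/2)` with `corr(z_a, z_b) = ρ` (default ρ = 0.95,
σ = 0.8) between the paired tracks; the element's expected total signal
(default 1000 reads) is spread uniformly over its bins on top of
Poisson(1) background. Tying total (rather than per-bin) intensity to the
latent factor makes the log-sum correlation estimate ≈ ρ independent of
element length, so the recovery analysis measures the intended parameter.
The DOT1Li track variant multiplies KEE signal by the global effect size.

Capture-C fragments are exponential (mean 250 bp, min 50 bp) — a stand-in
for a DpnII digest, not a real-genome digestion. Expected raw counts decay
as `μ = A(d + d0)^(−α)` (A = 6·10⁴, d0 = 2 kb, α = 1), ×6 inside
interaction peaks, ×`dot1li_effect` (default 0.4) at KEE peaks in the
treated condition only. Counts are negative binomial with
Var = μ + 0.1·μ², per-sample library factors Uniform(0.7, 1.3), and cis
totals are realized sums plus Poisson background (2·10⁵ · library factor).
These magnitudes were chosen to put per-fragment counts in the tens across
a ±100 kb domain — typical of deep Capture-C libraries — and are config,
not claims about any particular dataset. Under the null (effect 1.0) the
two conditions are exchangeable within pairs, so test calibration on this
generator checks the statistic, not the generator.

DE tables mark genes down with probability 0.33 (KEE genes) or 0.20
(others), up with 0.15, with FDR drawn consistent with status and a +1
log-expression shift for KEE genes. ATAC decreased peaks are planted inside
enhancers whose gene is down with probability 0.73 (KEEs) / 0.21
(non-KEEs). Spike-in pairs scale DOT1Li target-IP material by the true
global loss (default 0.1) at fixed spike material and re-sequence to equal
depth with optional Poisson noise.

All streams derive from one seed through named `SeedSequence` substreams,
so a fixed config is byte-reproducible file by file.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; overlap means ≥ 1 shared bp.
- Signed-rank exact/approximate switch at n = 25; rank-sum exact guard at
  min group ≤ 12 and N ≤ 60 (both configurable).
- `p ∉ [0,1]`, negative counts, zero cis totals, empty groups, peaks
  overlapping no fragment, and enhancer-bearing chromosomes without genes
  all raise errors naming the offender rather than propagating NaNs.
- Track equality and the scale/unscale round-trip are exact to 1e-9;
  bedGraph writing run-length-merges equal adjacent bins and clips the
  final bin to the chromosome end.

## Problem sizes used in the checked analyses

The shipped analyses run at desk scale: a 2 × 8 Mb genome with 300 genes
and 150 + 150 enhancers for classification; 5000 enhancers on a 4 × 10 Mb
genome for correlation recovery; 2000 null and 50 + 50 effect interaction
peaks (5 per probe family, 3 replicates) for calibration and recovery; DE
tables of 2000/1400 genes. These sizes give stable estimates (binomial SE
≲ 0.01 on rates) while keeping any single analysis in seconds.

## Known limitations

- Peak calling, read alignment, and count-model fitting (edgeR/DESeq-style)
  are out of scope; their outputs are inputs here.
- The generator's noise-free peaks cannot probe classifier robustness to
  peak-boundary error, and its power-law contact model is a stylization.
- The signed-rank pairs within one peak share fragments across replicates
  and are treated as independent, as in the original analysis design;
  strong inter-replicate correlation would make the test anticonservative
  (the null-calibration check covers the generator's regime only).
- Interaction-peak boundaries must be supplied or derived by the quantile
  caller; no claim is made that the caller reproduces hand-drawn domains.
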