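# keetools

Analysis toolkit for **H3K79me2/3 enhancer elements (KEEs)** — putative
enhancers that carry H3K79 di/trimethylation on top of the canonical
H3K4me1 + H3K27ac enhancer signature — and for measuring what happens to
them when the sole H3K79 methyltransferase DOT1L is inhibited (DOT1Li).
It is aimed at regulatory-genomics analysts working with histone-mark peak
calls, spike-in-normalized ChIP-seq (ChIP-rx), NG Capture-C fragment
counts, and differential expression/accessibility tables.

## What it computes

**Enhancer classification.** The genome is tiled into 200 bp buckets.
A bucket is a *KEE* bucket when it overlaps peaks of H3K4me1, H3K27ac and
H3K79me2 (or me3); a *non-KEE* bucket when it has H3K4me1 + H3K27ac but no
H3K79 peak. Enhancer buckets < 1 kb apart are merged; a merged enhancer is
a KEE if any constituent bucket was. Enhancers are annotated
intragenic/intergenic, assigned to the nearest gene, and genes are
labelled: ≥ 1 assigned KEE ⇒ *KEE gene* (regardless of non-KEE
association), otherwise ≥ 1 non-KEE ⇒ *non-KEE gene*.

**ChIP-rx normalization.** With spike-in read counts from IP and input
samples, the scale factor applied to a tags-per-10-million track is the
input-corrected spike ratio

```
factor = (n_spike_input / n_target_input) / (n_spike_ip / n_target_ip)
```

so a global loss of target signal (spike share of the IP rises) deflates
the track.

**Differential Capture-C.** Per-DpnII-fragment counts are normalized to
reads per 100 k cis-reported reads per replicate. Interaction peaks outside
the probe's interaction domain, on trans chromosomes, or within 10 kb of
the probe are removed. Each retained peak is tested with a paired Wilcoxon
signed-rank over the normalized counts of every overlapping fragment ×
replicate (replicate *i* control paired with replicate *i* DOT1Li): zero
differences dropped, midranks for ties, exact permutation p for n ≤ 25
pairs, else a tie-corrected normal approximation. p-values are
Holm–Bonferroni adjusted within each probe's retained-peak family. A
signed per-fragment differential track (sliding mean over fragments) is
emitted alongside.

**Integration statistics.** Mark–mark Pearson correlation of log2(x+1)
read sums at enhancers, KEE- vs non-KEE-gene expression comparison
(Wilcoxon rank-sum, exact for small groups), DE-status × enhancer-class
contingency tables with an exact-rational Fisher's exact test, the ATAC
direction × enhancer class × transcription cross-tabulation, and
scaled-body metaprofiles.

**Synthetic data.** A fully seeded generator produces every input above
with known ground truth (true KEEs, true interaction effects, true DE
proportions), enabling exact recovery tests; see `docs/methods.md`.

## Worked example

```
kee simulate --seed 7 --outdir sim
kee classify --h3k4me1 sim/peaks_h3k4me1.bed --h3k27ac sim/peaks_h3k27ac.bed \
    --h3k79 sim/peaks_h3k79me2.bed --genes sim/genes.tsv \
    --chrom-sizes sim/chrom.sizes --out-prefix cls
kee rxnorm --counts sim/spikein.tsv --track sim/track_h3k79me3.bedgraph \
    --out h3k79me3.rx.bedgraph
kee capdiff --counts sim/capture_counts.tsv --design sim/capture_design.tsv \
    --peaks sim/capture_peaks.bed --enhancers cls.enhancers.bed --out-prefix cap
kee integrate --enhancers cls.enhancers.bed --gene-labels cls.gene_labels.tsv \
    --de sim/de.tsv --atac sim/atac.tsv --genes sim/genes.tsv \
    --tracks sim/track_h3k79me2.bedgraph sim/track_h3k79me3.bedgraph \
    --metaprofile --out-prefix intg
```

This prints:

```
simulation written to sim
300 enhancers called
rx factor for dot1li: 0.0445026
46 peaks tested, 20 significant (Holm < 0.05)
integration summary written to intg.summary.json
```

Reading the output: all 300 planted enhancers are recovered with their
classes (`cls.summary.json` reports median lengths 1.0 kb for KEEs and
0.8 kb for non-KEEs). The DOT1Li rx factor of 0.045 reflects the simulated
near-complete global loss of H3K79me3. Of the tested enhancer–promoter
peaks, the Holm-significant ones are the KEE interactions the generator
attenuated, while non-KEE interactions stay flat (`cap.results.tsv` has
per-peak means, deltas and adjusted p-values). `intg.summary.json` shows
the me2/me3 mark correlation at enhancers (r ≈ 0.95), the higher
down-regulation rate of KEE genes with its Fisher p, and the
decreased-ATAC/transcription concordance split by enhancer class.

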