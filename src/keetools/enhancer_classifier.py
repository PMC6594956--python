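"""KEE / non-KEE enhancer classification from histone-mark peak calls.

The genome is tiled into fixed-width buckets (200 bp by default).  A bucket
is a KEE bucket when it overlaps peaks of all three marks — H3K4me1, H3K27ac
and H3K79me2 (or me3) — and a non-KEE bucket when it overlaps H3K4me1 and
H3K27ac but no H3K79 peak.  Enhancer buckets less than 1 kb apart (strict <)
are merged into one enhancer, which is labelled a KEE if any constituent
bucket is a KEE bucket.  Enhancers are annotated intragenic/intergenic by
gene-body overlap, assigned to the nearest gene, and genes are labelled:
a gene with at least one assigned KEE is a KEE gene regardless of how many
non-KEEs it also carries; a gene with only non-KEEs is a non-KEE gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    PeakSet,
    nearest,
    overlaps,
)

STATE_NONE = 0
STATE_NONKEE = 1
STATE_KEE = 2

KEE = "KEE"
NONKEE = "nonKEE"


@dataclass(frozen=True)
class BucketClassification:
    bucket: GenomicInterval
    state: str  # "KEE" | "nonKEE" | "none"


@dataclass
class BucketStates:
    """Per-chromosome bucket state codes (dense int8 arrays)."""

    chrom_sizes: ChromSizes
    width: int
    states: dict[str, np.ndarray]

    def to_records(self) -> list[BucketClassification]:
        names = {STATE_NONE: "none", STATE_NONKEE: NONKEE, STATE_KEE: KEE}
        out = []
        for chrom, arr in self.states.items():
            clen = self.chrom_sizes[chrom]
            for i, code in enumerate(arr):
                out.append(
                    BucketClassification(
                        GenomicInterval(
                            chrom, i * self.width, min((i + 1) * self.width, clen)
                        ),
                        names[int(code)],
                    )
                )
        return out


@dataclass
class EnhancerCall:
    """A merged enhancer with class, location and nearest-gene assignment."""

    interval: GenomicInterval
    klass: str  # "KEE" | "nonKEE"
    location: str | None = None  # "intragenic" | "intergenic"
    gene_id: str | None = None
    gene_distance: int | None = None
    n_kee_buckets: int = 0
    n_nonkee_buckets: int = 0


@dataclass(frozen=True)
class GeneEnhancerLabel:
    gene_id: str
    label: str  # "KEE_gene" | "nonKEE_gene" | "none"
    h3k79_marked: bool = False


def bucketize(
    chrom_sizes: ChromSizes, width: int = 200
) -> list[GenomicInterval]:
    """Tile each chromosome into width-bp buckets; the last may be shorter."""
    if width <= 0:
        raise ValueError("bucket width must be positive")
    out = []
    for chrom, clen in chrom_sizes.items():
        for start in range(0, clen, width):
            out.append(GenomicInterval(chrom, start, min(start + width, clen)))
    return out


def _coverage(
    peaks: PeakSet, chrom_sizes: ChromSizes, width: int
) -> dict[str, np.ndarray]:
    """Boolean per-bucket coverage: bucket covered iff >= 1 bp peak overlap."""
    cov = {
        chrom: np.zeros(-(-clen // width), dtype=bool)
        for chrom, clen in chrom_sizes.items()
    }
    for iv in peaks:
        if iv.chrom not in cov:
            raise ValueError(f"peak on unknown chromosome {iv.chrom!r}")
        arr = cov[iv.chrom]
        lo = iv.start // width
        hi = min(-(-iv.end // width), len(arr))
        arr[lo:hi] = True
    return cov


def classify_buckets(
    chrom_sizes: ChromSizes,
    peaks: Mapping[str, PeakSet],
    width: int = 200,
) -> BucketStates:
    """Classify every genome bucket from mark-presence.

    ``peaks`` must provide keys ``"H3K4me1"``, ``"H3K27ac"`` and ``"H3K79"``
    (the latter holding either the me2 or the me3 peak set — caller's choice).
    Any additional mark keys are accepted and ignored by the rule.
    """
    for key in ("H3K4me1", "H3K27ac", "H3K79"):
        if key not in peaks:
            raise ValueError(f"missing required peak set {key!r}")
    k4 = _coverage(peaks["H3K4me1"], chrom_sizes, width)
    k27 = _coverage(peaks["H3K27ac"], chrom_sizes, width)
    k79 = _coverage(peaks["H3K79"], chrom_sizes, width)
    states = {}
    for chrom in chrom_sizes:
        enh = k4[chrom] & k27[chrom]
        arr = np.zeros(len(enh), dtype=np.int8)
        arr[enh & k79[chrom]] = STATE_KEE
        arr[enh & ~k79[chrom]] = STATE_NONKEE
        states[chrom] = arr
    return BucketStates(chrom_sizes, width, states)


def call_enhancers(
    states: BucketStates, merge_gap: int = 1000
) -> list[EnhancerCall]:
    """Merge enhancer-bucket runs < merge_gap bp apart into enhancer calls.

    A merged call is a KEE iff any constituent bucket is a KEE bucket; its
    interval spans the first bucket start to the last bucket end.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    w = states.width
    calls: list[EnhancerCall] = []
    for chrom in states.chrom_sizes:
        arr = states.states[chrom]
        clen = states.chrom_sizes[chrom]
        idx = np.flatnonzero(arr != STATE_NONE)
        if len(idx) == 0:
            continue
        # split where the bp gap between consecutive enhancer buckets
        # ((b - prev - 1) * w) is >= merge_gap (strict-< merge rule)
        breaks = np.flatnonzero((np.diff(idx) - 1) * w >= merge_gap)
        groups = np.split(idx, breaks + 1)
        for g in groups:
            n_kee = int(np.sum(arr[g] == STATE_KEE))
            n_non = int(np.sum(arr[g] == STATE_NONKEE))
            calls.append(
                EnhancerCall(
                    interval=GenomicInterval(
                        chrom, int(g[0]) * w, min((int(g[-1]) + 1) * w, clen)
                    ),
                    klass=KEE if n_kee >= 1 else NONKEE,
                    n_kee_buckets=n_kee,
                    n_nonkee_buckets=n_non,
                )
            )
    return calls


def annotate_location(
    enhancers: Sequence[EnhancerCall], genes: Sequence[GeneModel]
) -> list[EnhancerCall]:
    """Label each enhancer intragenic (>= 1 bp gene-body overlap) or intergenic."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for e in enhancers:
        hit = any(
            overlaps(e.interval, g.interval)
            for g in by_chrom.get(e.interval.chrom, ())
        )
        out.append(replace_call(e, location="intragenic" if hit else "intergenic"))
    return out


def replace_call(call: EnhancerCall, **kw) -> EnhancerCall:
    d = dict(
        interval=call.interval,
        klass=call.klass,
        location=call.location,
        gene_id=call.gene_id,
        gene_distance=call.gene_distance,
        n_kee_buckets=call.n_kee_buckets,
        n_nonkee_buckets=call.n_nonkee_buckets,
    )
    d.update(kw)
    return EnhancerCall(**d)


def assign_genes(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel],
    reference: str = "body",
) -> list[EnhancerCall]:
    """Assign each enhancer to its nearest gene (distance 0 when intragenic)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    missing = sorted(
        {e.interval.chrom for e in enhancers} - set(by_chrom)
    )
    if missing:
        raise ValueError(
            f"chromosome(s) with enhancers but no genes: {', '.join(missing)}"
        )
    out = []
    for e in enhancers:
        gene, dist = nearest(e.interval, by_chrom[e.interval.chrom], reference)
        out.append(replace_call(e, gene_id=gene.gene_id, gene_distance=dist))
    return out


def label_genes(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel] | None = None,
    h3k79_marked: Mapping[str, bool] | None = None,
) -> list[GeneEnhancerLabel]:
    """Label genes from their assigned enhancers.

    A gene with >= 1 assigned KEE is a KEE gene (even if it also has
    non-KEEs); with >= 1 assigned non-KEE and no KEE it is a non-KEE gene.
    Genes with no assigned enhancer get label "none".
    """
    kee_genes: set[str] = set()
    nonkee_genes: set[str] = set()
    for e in enhancers:
        if e.gene_id is None:
            raise ValueError("enhancers must be gene-assigned before labelling")
        (kee_genes if e.klass == KEE else nonkee_genes).add(e.gene_id)
    gene_ids = (
        [g.gene_id for g in genes]
        if genes is not None
        else sorted(kee_genes | nonkee_genes)
    )
    marked = h3k79_marked or {}
    out = []
    for gid in gene_ids:
        if gid in kee_genes:
            label = "KEE_gene"
        elif gid in nonkee_genes:
            label = "nonKEE_gene"
        else:
            label = "none"
        out.append(GeneEnhancerLabel(gid, label, bool(marked.get(gid, False))))
    return out


def mark_h3k79_genes(
    genes: Sequence[GeneModel], h3k79_peaks: PeakSet
) -> dict[str, bool]:
    """True iff the gene body overlaps >= 1 H3K79 peak (body only, not promoter)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in h3k79_peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return {
        g.gene_id: any(
            overlaps(g.interval, iv) for iv in by_chrom.get(g.chrom, ())
        )
        for g in genes
    }


def filter_promoter_overlaps(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel] | None = None,
    h3k4me3: PeakSet | None = None,
    tss_window: int = 2000,
) -> list[EnhancerCall]:
    """Optional promoter-exclusion filter (off by default in the pipeline).

    Drops enhancers overlapping an H3K4me3 peak and/or a TSS +/- tss_window
    region.  Provided because promoter-proximal H3K4me3-high elements are
    conventionally excluded from enhancer sets; the core classification rule
    does not apply it.
    """
    excl: dict[str, list[GenomicInterval]] = {}
    if h3k4me3 is not None:
        for iv in h3k4me3:
            excl.setdefault(iv.chrom, []).append(iv)
    if genes is not None:
        for g in genes:
            lo = max(0, g.tss - tss_window)
            excl.setdefault(g.chrom, []).append(
                GenomicInterval(g.chrom, lo, g.tss + tss_window + 1)
            )
    return [
        e
        for e in enhancers
        if not any(
            overlaps(e.interval, iv) for iv in excl.get(e.interval.chrom, ())
        )
    ]


def kee_fraction_summary(enhancers: Sequence[EnhancerCall]) -> dict:
    """Per-class counts, proportions, median lengths and intragenic fractions."""
    if not enhancers:
        raise ValueError("no enhancer calls to summarize")
    out: dict = {"n_total": len(enhancers)}
    for klass in (KEE, NONKEE):
        sub = [e for e in enhancers if e.klass == klass]
        entry: dict = {"n": len(sub), "proportion": len(sub) / len(enhancers)}
        if sub:
            entry["median_length_bp"] = float(
                np.median([e.interval.length for e in sub])
            )
            located = [e for e in sub if e.location is not None]
            if located:
                entry["intragenic_fraction"] = sum(
                    e.location == "intragenic" for e in located
                ) / len(located)
        out[klass] = entry
    return out
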