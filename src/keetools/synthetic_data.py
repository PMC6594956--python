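"""Seeded synthetic-data generator for the whole pipeline.

Produces every input the analysis consumes — genome + gene models, histone
mark peak calls with known KEE/non-KEE ground truth, latent-correlated
binned signal tracks, distance-decaying negative-binomial Capture-C fragment
counts with enhancer-localized interaction peaks attenuated at KEEs only
under "DOT1Li", differential-expression tables in which KEE genes are
preferentially downregulated, ATAC-direction tables, and target/spike-in
read-count pairs — plus a :class:`GroundTruthManifest` recording the truth
for recovery tests.

All randomness flows from one seed through named `numpy` substreams, so a
fixed :class:`SimConfig` yields byte-identical output files.

What the generator emulates, and what it does not: peak calls are emitted
exactly at true elements (optionally with me2/me3 disagreement), so
classifier recovery is exact by construction; real peak callers add boundary
noise.  Capture-C counts follow a power-law contact-decay with negative
binomial dispersion, a standard stylization of 3C profiles, not a model fit
to any particular library.  Fragment maps are exponential stand-ins for a
DpnII digest of a real genome.
"""
from __future__ import annotations

import dataclasses
import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .capturec_diff import (
    CONTROL,
    DOT1LI,
    CaptureDesign,
    FragmentCountMatrix,
    write_capture_design,
    write_fragment_counts,
)
from .chiprx_norm import SpikeInCounts, write_spikein_table
from .enhancer_classifier import KEE, NONKEE, GeneEnhancerLabel
from .genomic_io import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    nearest,
    write_bed,
    write_bedgraph,
    write_gene_table,
)

BUCKET = 200  # bp; matches the classifier's genome bucketing


@dataclass
class CaptureSimConfig:
    """Capture-C generator block.

    ``baseline`` (A), ``decay_scale`` (d0, bp) and ``decay_exponent`` (alpha)
    set the expected raw count mu = A*(d+d0)^(-alpha) at fragment distance d
    from the probe; ``peak_boost`` multiplies mu inside interaction peaks and
    ``dot1li_effect`` multiplies KEE-peak fragments in the treated condition
    only (1.0 = null).  Counts are negative binomial with variance
    mu + dispersion*mu^2; per-sample library factors are uniform on
    ``library_size_range`` and ``background_cis`` adds non-peak cis depth to
    the per-sample totals.
    """

    n_probes: int = 6
    domain_halfwidth: int = 100_000
    mean_fragment_bp: int = 250
    min_fragment_bp: int = 50
    decay_exponent: float = 1.0
    decay_scale: float = 2000.0
    baseline: float = 60_000.0
    peak_boost: float = 6.0
    dot1li_effect: float = 0.4
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    library_size_range: tuple[float, float] = (0.7, 1.3)
    background_cis: float = 200_000.0
    peak_fragments: int = 12
    exclusion_radius: int = 10_000


@dataclass
class DESimConfig:
    """Differential-expression generator block (probabilities by true label)."""

    p_down_kee: float = 0.33
    p_down_nonkee: float = 0.20
    p_up: float = 0.15
    log2fc_mean: float = 1.0
    log2fc_sd: float = 0.4
    expression_base: float = 3.0
    expression_sd: float = 1.0
    kee_expression_shift: float = 1.0


@dataclass
class AtacSimConfig:
    """ATAC generator block: decreased peaks are planted inside enhancers
    whose assigned gene is transcriptionally down with the stated
    concordance probability per class."""

    n_decreased_kee: int = 200
    n_decreased_nonkee: int = 200
    p_down_given_decreased_kee: float = 0.73
    p_down_given_decreased_nonkee: float = 0.21
    n_increased: int = 50
    n_unchanged: int = 200


@dataclass
class SpikeInSimConfig:
    """Spike-in generator block; ``true_global_loss`` is the DOT1Li-induced
    global loss of target IP material (factor ratio recovered by ChIP-rx)."""

    true_global_loss: float = 0.1
    n_target_ip: float = 8e6
    n_spike_ip: float = 2e6
    n_target_input: float = 9e6
    n_spike_input: float = 1e6
    noisy: bool = True


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 8_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    n_kee: int = 150
    n_nonkee: int = 150
    frac_intragenic: float = 0.7
    kee_median_length: int = 1_000
    nonkee_median_length: int = 800
    length_log_sd: float = 0.5
    me2_me3_agreement: float = 0.97
    p_gene_body_h3k79: float = 0.6
    track_bg_rate: float = 1.0
    track_peak_reads: float = 1_000.0
    latent_mark_correlation: float = 0.95
    latent_sigma: float = 0.8
    capture: CaptureSimConfig = field(default_factory=CaptureSimConfig)
    de: DESimConfig = field(default_factory=DESimConfig)
    atac: AtacSimConfig = field(default_factory=AtacSimConfig)
    spikein: SpikeInSimConfig = field(default_factory=SpikeInSimConfig)

    def __post_init__(self) -> None:
        for name in ("frac_intragenic", "me2_me3_agreement", "p_gene_body_h3k79"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.capture.dot1li_effect <= 1:
            raise ValueError("dot1li_effect must lie in (0, 1]")
        if self.capture.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.track_bg_rate <= 0 or self.track_peak_reads < 0:
            raise ValueError("track rates must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key, sub in (
            ("capture", CaptureSimConfig),
            ("de", DESimConfig),
            ("atac", AtacSimConfig),
            ("spikein", SpikeInSimConfig),
        ):
            if key in d and isinstance(d[key], Mapping):
                d[key] = sub(**d[key])
        for key in ("gene_length_range",):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return enc(self)


@dataclass(frozen=True)
class TrueEnhancer:
    interval: GenomicInterval
    klass: str  # KEE | nonKEE
    location: str  # intragenic | intergenic
    gene_id: str


@dataclass(frozen=True)
class TrueCapturePeak:
    probe_id: str
    interval: GenomicInterval
    klass: str
    effect: float  # dot1li multiplier actually applied (e at KEEs, 1 else)


@dataclass
class GroundTruthManifest:
    """Everything the recovery tests need: true elements and parameters."""

    config: SimConfig
    enhancers: list[TrueEnhancer] = field(default_factory=list)
    gene_labels: dict[str, str] = field(default_factory=dict)
    h3k79_marked: dict[str, bool] = field(default_factory=dict)
    de_status: dict[str, str] = field(default_factory=dict)
    capture_peaks: list[TrueCapturePeak] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "config": self.config.to_dict(),
            "enhancers": [
                {
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "klass": e.klass,
                    "location": e.location,
                    "gene_id": e.gene_id,
                }
                for e in self.enhancers
            ],
            "gene_labels": self.gene_labels,
            "h3k79_marked": self.h3k79_marked,
            "de_status": self.de_status,
            "capture_peaks": [
                {
                    "probe_id": p.probe_id,
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "klass": p.klass,
                    "effect": p.effect,
                }
                for p in self.capture_peaks
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


_STREAMS = (
    "genome",
    "enhancers",
    "tracks",
    "capture",
    "de",
    "atac",
    "spikein",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG stream for one output family."""
    if name not in _STREAMS:
        raise KeyError(f"unknown stream {name!r}")
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(name)])


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(
    config: SimConfig,
) -> tuple[ChromSizes, list[GeneModel]]:
    """Non-overlapping genes packed left-to-right with random spacing."""
    rng = substream(config.seed, "genome")
    chroms = [f"chrS{i + 1}" for i in range(config.n_chroms)]
    sizes = ChromSizes({c: config.chrom_length_bp for c in chroms})
    genes: list[GeneModel] = []
    per_chrom = -(-config.n_genes // config.n_chroms) if config.n_chroms else 0
    lo, hi = config.gene_length_range
    gid = 0
    for chrom in chroms:
        cursor = int(rng.integers(2_000, 10_000))
        placed = 0
        while placed < per_chrom and gid < config.n_genes:
            length = int(rng.integers(lo, hi + 1))
            if cursor + length > config.chrom_length_bp - 2_000:
                break
            gid += 1
            placed += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    gene_name=f"GENE{gid}",
                    interval=GenomicInterval(
                        chrom, cursor, cursor + length, strand, name=f"G{gid:05d}"
                    ),
                )
            )
            cursor += length + int(rng.integers(3_000, 25_000))
    if gid < config.n_genes:
        raise ValueError(
            f"could not place {config.n_genes} genes on "
            f"{config.n_chroms} x {config.chrom_length_bp} bp"
        )
    return sizes, genes


# ---------------------------------------------------------------------------
# enhancers and peaks
# ---------------------------------------------------------------------------

def _snap(start: float, length_bp: float) -> tuple[int, int]:
    """Align an element to the classifier's bucket grid."""
    s = int(start) // BUCKET * BUCKET
    n = max(1, int(round(length_bp / BUCKET)))
    return s, s + n * BUCKET

# minimum edge-to-edge gap between distinct true enhancers; above the 1 kb
# merge gap so the classifier never fuses two of them
_MIN_SEPARATION = 1_200


class _Placer:
    """Per-chromosome occupied-interval bookkeeping with bisect lookups."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def fits(self, chrom: str, start: int, end: int, min_gap: int) -> bool:
        ivs = self.by_chrom.get(chrom, [])
        i = bisect_left(ivs, (start, end))
        if i > 0 and start - ivs[i - 1][1] < min_gap:
            return False
        if i < len(ivs) and ivs[i][0] - end < min_gap:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self.by_chrom.setdefault(chrom, []), (start, end))


def simulate_enhancers_and_peaks(
    config: SimConfig,
    chrom_sizes: ChromSizes,
    genes: Sequence[GeneModel],
) -> tuple[dict[str, PeakSet], list[TrueEnhancer]]:
    """Emit H3K4me1/H3K27ac/H3K79me2/H3K79me3 peaks with known ground truth.

    Every true KEE emits all three marks (me3 copies me2 with probability
    ``me2_me3_agreement``); true non-KEEs emit only H3K4me1+H3K27ac.
    Gene-body H3K79 blocks are additionally emitted over a random subset of
    genes (carved around any hosted non-KEE enhancer), so gene-body marking
    is decoupled from enhancer marking.
    """
    rng = substream(config.seed, "enhancers")
    placer = _Placer()
    chroms = list(chrom_sizes)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    def draw_length(median: int) -> float:
        return median * float(np.exp(rng.normal(0.0, config.length_log_sd)))

    truths: list[TrueEnhancer] = []
    specs = [(KEE, config.n_kee), (NONKEE, config.n_nonkee)]
    host_gene: dict[int, GeneModel | None] = {}
    for klass, count in specs:
        median = (
            config.kee_median_length if klass == KEE else config.nonkee_median_length
        )
        for _ in range(count):
            placed = False
            for _attempt in range(400):
                length = draw_length(median)
                intragenic = bool(genes) and rng.random() < config.frac_intragenic
                if intragenic:
                    gene = genes[int(rng.integers(len(genes)))]
                    body_lo = gene.interval.start + BUCKET
                    body_hi = gene.interval.end - BUCKET
                    if body_hi - body_lo < length + 2 * BUCKET:
                        continue
                    pos = rng.uniform(body_lo, body_hi - length)
                    start, end = _snap(pos, length)
                    if start < body_lo or end > body_hi:
                        continue
                    location, host = "intragenic", gene
                    chrom = gene.chrom
                else:
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    pos = rng.uniform(
                        2 * BUCKET, chrom_sizes[chrom] - length - 2 * BUCKET
                    )
                    start, end = _snap(pos, length)
                    # intergenic elements must clear gene bodies by >=1 bucket
                    clash = any(
                        g.interval.start - BUCKET < end
                        and start < g.interval.end + BUCKET
                        for g in genes_by_chrom.get(chrom, ())
                    )
                    if clash:
                        continue
                    location, host = "intergenic", None
                if not placer.fits(chrom, start, end, _MIN_SEPARATION):
                    continue
                placer.add(chrom, start, end)
                iv = GenomicInterval(chrom, start, end)
                if host is not None:
                    gene_id = host.gene_id
                else:
                    cands = genes_by_chrom.get(chrom)
                    gene_id = nearest(iv, cands)[0].gene_id if cands else ""
                truths.append(TrueEnhancer(iv, klass, location, gene_id))
                host_gene[len(truths) - 1] = host
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place {klass} enhancer after 400 attempts; "
                    "genome too crowded"
                )

    k4, k27, me2, me3 = [], [], [], []
    for t in truths:
        k4.append(t.interval)
        k27.append(t.interval)
        if t.klass == KEE:
            me2.append(t.interval)
            if rng.random() < config.me2_me3_agreement:
                me3.append(t.interval)

    # gene-body H3K79 blocks over a random gene subset, carved around
    # hosted non-KEE enhancers (with a one-bucket margin) so no non-KEE
    # bucket ever sees H3K79 signal
    nonkee_by_gene: dict[str, list[GenomicInterval]] = {}
    for t in truths:
        if t.klass == NONKEE and t.location == "intragenic":
            nonkee_by_gene.setdefault(t.gene_id, []).append(t.interval)
    body_blocks: list[GenomicInterval] = []
    for g in genes:
        if rng.random() >= config.p_gene_body_h3k79:
            continue
        lo = -(-g.interval.start // BUCKET) * BUCKET  # ceil to grid
        hi = g.interval.end // BUCKET * BUCKET
        if hi - lo < BUCKET:
            continue
        cuts = sorted(
            (max(lo, e.start - BUCKET), min(hi, e.end + BUCKET))
            for e in nonkee_by_gene.get(g.gene_id, [])
        )
        cursor = lo
        for c_lo, c_hi in cuts:
            if c_lo - cursor >= BUCKET:
                body_blocks.append(GenomicInterval(g.chrom, cursor, c_lo))
            cursor = max(cursor, c_hi)
        if hi - cursor >= BUCKET:
            body_blocks.append(GenomicInterval(g.chrom, cursor, hi))
    me2.extend(body_blocks)
    me3.extend(body_blocks)

    peaks = {
        "H3K4me1": PeakSet("H3K4me1", k4),
        "H3K27ac": PeakSet("H3K27ac", k27),
        "H3K79me2": PeakSet("H3K79me2", me2),
        "H3K79me3": PeakSet("H3K79me3", me3),
    }
    return peaks, truths


def true_gene_labels(
    truths: Sequence[TrueEnhancer], genes: Sequence[GeneModel]
) -> dict[str, str]:
    """Expected gene labels from the manifest (KEE precedence rule)."""
    kee = {t.gene_id for t in truths if t.klass == KEE}
    non = {t.gene_id for t in truths if t.klass == NONKEE}
    out = {}
    for g in genes:
        if g.gene_id in kee:
            out[g.gene_id] = "KEE_gene"
        elif g.gene_id in non:
            out[g.gene_id] = "nonKEE_gene"
        else:
            out[g.gene_id] = "none"
    return out


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    config: SimConfig,
    truths: Sequence[TrueEnhancer],
    chrom_sizes: ChromSizes,
    rng: np.random.Generator | None = None,
    rho: float | None = None,
    attenuate_kee: float = 1.0,
    kee_only: bool = False,
) -> tuple[SignalTrack, SignalTrack]:
    """A pair of 200-bp binned count tracks with latent-correlated enhancer
    signal.

    Each enhancer carries a latent strength L = exp(sigma*z - sigma^2/2)
    with corr(z_a, z_b) = rho between the two tracks; its expected total
    signal ``track_peak_reads * L`` is spread uniformly over the element's
    bins on top of Poisson background.  ``attenuate_kee`` multiplies
    KEE-element signal in the second track only (the DOT1Li analogue);
    ``kee_only`` restricts enhancer signal to KEE elements.
    """
    if rng is None:
        rng = substream(config.seed, "tracks")
    if rho is None:
        rho = config.latent_mark_correlation
    if not 0 <= rho <= 1:
        raise ValueError("latent correlation must lie in [0, 1]")
    sigma = config.latent_sigma
    w = BUCKET
    arrays_a, arrays_b = {}, {}
    for chrom, clen in chrom_sizes.items():
        n = -(-clen // w)
        arrays_a[chrom] = rng.poisson(config.track_bg_rate, n).astype(float)
        arrays_b[chrom] = rng.poisson(config.track_bg_rate, n).astype(float)
    sq_r, sq_1r = np.sqrt(rho), np.sqrt(1 - rho)
    for t in truths:
        if kee_only and t.klass != KEE:
            continue
        g = rng.normal()
        za = sq_r * g + sq_1r * rng.normal()
        zb = sq_r * g + sq_1r * rng.normal()
        la = np.exp(sigma * za - sigma**2 / 2)
        lb = np.exp(sigma * zb - sigma**2 / 2)
        lo, hi = t.interval.start // w, t.interval.end // w
        nb = hi - lo
        rate_a = config.track_peak_reads * la / nb
        rate_b = config.track_peak_reads * lb / nb
        if t.klass == KEE:
            rate_b *= attenuate_kee
        arrays_a[t.interval.chrom][lo:hi] += rng.poisson(rate_a, nb)
        arrays_b[t.interval.chrom][lo:hi] += rng.poisson(rate_b, nb)
    return SignalTrack(w, arrays_a), SignalTrack(w, arrays_b)


# ---------------------------------------------------------------------------
# Capture-C
# ---------------------------------------------------------------------------

def _fragment_map(
    cap: CaptureSimConfig,
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
) -> list[GenomicInterval]:
    """Consecutive pseudo-DpnII fragments tiling [lo, hi)."""
    frags = []
    cursor = lo
    mean_extra = max(1, cap.mean_fragment_bp - cap.min_fragment_bp)
    while cursor < hi:
        length = cap.min_fragment_bp + int(rng.exponential(mean_extra))
        end = min(cursor + length, hi)
        if end - cursor >= cap.min_fragment_bp or end == hi:
            frags.append(GenomicInterval(chrom, cursor, max(end, cursor + 1)))
        cursor = end
    return frags


def expected_contact(cap: CaptureSimConfig, distance_bp: float) -> float:
    """Power-law contact decay: mu = A * (d + d0) ** (-alpha)."""
    return cap.baseline * (distance_bp + cap.decay_scale) ** (-cap.decay_exponent)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(float)


def _simulate_probe(
    cap: CaptureSimConfig,
    rng: np.random.Generator,
    probe_id: str,
    chrom: str,
    probe_pos: int,
    peak_classes: Sequence[str],
    peak_intervals: Sequence[GenomicInterval] | None = None,
) -> tuple[CaptureDesign, FragmentCountMatrix, list[TrueCapturePeak], list[GenomicInterval]]:
    lo = max(0, probe_pos - cap.domain_halfwidth)
    hi = probe_pos + cap.domain_halfwidth
    if hi - lo < 4 * (cap.exclusion_radius + cap.peak_fragments * cap.mean_fragment_bp):
        raise ValueError("capture domain too small for probe + exclusion zone")
    design = CaptureDesign(
        probe_id=probe_id,
        probe=GenomicInterval(chrom, probe_pos - 60, probe_pos + 60),
        domain=GenomicInterval(chrom, lo, hi),
        exclusion_radius=cap.exclusion_radius,
        n_replicates=cap.n_replicates,
    )
    frags = _fragment_map(cap, rng, chrom, lo, hi)
    n_frag = len(frags)
    mids = np.array([f.midpoint for f in frags])
    dist = np.abs(mids - probe_pos)
    mu = expected_contact(cap, dist)

    truths: list[TrueCapturePeak] = []
    boost = np.ones(n_frag)
    effect = np.ones(n_frag)
    if peak_intervals is not None:
        peak_spans = list(peak_intervals)
        assert len(peak_spans) == len(peak_classes)
        for span, klass in zip(peak_spans, peak_classes):
            sel = [
                i
                for i, f in enumerate(frags)
                if f.start < span.end and span.start < f.end
            ]
            if not sel:
                continue
            boost[sel] = cap.peak_boost
            if klass == KEE:
                effect[sel] = cap.dot1li_effect
            truths.append(
                TrueCapturePeak(
                    probe_id,
                    span,
                    klass,
                    cap.dot1li_effect if klass == KEE else 1.0,
                )
            )
    else:
        # place each requested peak as a run of peak_fragments fragments,
        # clear of the probe exclusion zone and of other peaks
        margin = cap.exclusion_radius + 3_000
        eligible = np.flatnonzero(dist > margin)
        taken: set[int] = set()
        for klass in peak_classes:
            for _attempt in range(200):
                start_i = int(eligible[int(rng.integers(len(eligible)))])
                idx = list(range(start_i, min(start_i + cap.peak_fragments, n_frag)))
                if len(idx) < cap.peak_fragments:
                    continue
                if any(i in taken for i in idx):
                    continue
                if dist[idx].min() <= cap.exclusion_radius + 500:
                    continue
                span = GenomicInterval(chrom, frags[idx[0]].start, frags[idx[-1]].end)
                if span.start < lo or span.end > hi:
                    continue
                taken.update(idx)
                boost[idx] = cap.peak_boost
                if klass == KEE:
                    effect[idx] = cap.dot1li_effect
                truths.append(
                    TrueCapturePeak(
                        probe_id,
                        span,
                        klass,
                        cap.dot1li_effect if klass == KEE else 1.0,
                    )
                )
                break
            else:
                raise ValueError(
                    f"could not place interaction peak in probe {probe_id}"
                )

    counts = np.zeros((n_frag, cap.n_replicates, 2))
    totals = np.zeros((cap.n_replicates, 2))
    s_lo, s_hi = cap.library_size_range
    for r in range(cap.n_replicates):
        for k, cond in enumerate((CONTROL, DOT1LI)):
            s = rng.uniform(s_lo, s_hi)
            cond_mu = mu * boost * (effect if cond == DOT1LI else 1.0) * s
            counts[:, r, k] = _nb_draw(rng, cond_mu, cap.nb_dispersion)
            totals[r, k] = counts[:, r, k].sum() + rng.poisson(
                cap.background_cis * s
            )
    matrix = FragmentCountMatrix(frags, counts, totals)
    return design, matrix, truths, [t.interval for t in truths]


def simulate_capture_panel(
    config: SimConfig,
    n_kee: int,
    n_nonkee: int,
    peaks_per_probe: int = 5,
    rng: np.random.Generator | None = None,
    chrom: str = "chrCap",
) -> tuple[dict[str, CaptureDesign], dict[str, FragmentCountMatrix], list[TrueCapturePeak]]:
    """A standalone probe panel with a controlled KEE/non-KEE peak mix.

    Classes are interleaved across probes so each Holm family holds a
    mixture.  Used for calibration and recovery runs where the peak census
    must be exact.
    """
    if rng is None:
        rng = substream(config.seed, "capture")
    classes = [KEE] * n_kee + [NONKEE] * n_nonkee
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]
    designs: dict[str, CaptureDesign] = {}
    matrices: dict[str, FragmentCountMatrix] = {}
    truths: list[TrueCapturePeak] = []
    cap = config.capture
    pos = cap.domain_halfwidth + 10_000
    stride = 2 * cap.domain_halfwidth + 50_000
    i = 0
    probe_n = 0
    while i < len(classes):
        chunk = classes[i : i + peaks_per_probe]
        i += len(chunk)
        probe_n += 1
        probe_id = f"P{probe_n:04d}"
        design, matrix, t, _ = _simulate_probe(
            cap, rng, probe_id, chrom, pos, chunk
        )
        designs[probe_id] = design
        matrices[probe_id] = matrix
        truths.extend(t)
        pos += stride
    return designs, matrices, truths


def simulate_capturec(
    config: SimConfig,
    genes: Sequence[GeneModel],
    truths: Sequence[TrueEnhancer],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, CaptureDesign], dict[str, FragmentCountMatrix], list[TrueCapturePeak]]:
    """Genome-integrated Capture-C: probes at TSSs of genes whose domain
    contains at least one true enhancer outside the exclusion zone; peaks
    are the enhancer intervals (padded to cover enough fragments)."""
    if rng is None:
        rng = substream(config.seed, "capture")
    cap = config.capture
    pad = max(0, (cap.peak_fragments * cap.mean_fragment_bp) // 2)
    by_chrom: dict[str, list[TrueEnhancer]] = {}
    for t in truths:
        by_chrom.setdefault(t.interval.chrom, []).append(t)

    candidates = []
    for g in genes:
        tss = g.tss
        if tss - cap.domain_halfwidth < 0:
            continue
        near = [
            t
            for t in by_chrom.get(g.chrom, ())
            if abs(t.interval.midpoint - tss) < cap.domain_halfwidth - pad - 2_000
            and abs(t.interval.midpoint - tss) > cap.exclusion_radius + pad + 2_000
        ]
        if near:
            candidates.append((g, near))
    if not candidates:
        raise ValueError("no gene has an enhancer within capture range")
    pick = rng.permutation(len(candidates))[: cap.n_probes]
    designs, matrices, out_truths = {}, {}, []
    for j in pick:
        gene, near = candidates[int(j)]
        spans = [
            GenomicInterval(
                t.interval.chrom,
                max(0, t.interval.start - pad),
                t.interval.end + pad,
            )
            for t in near
        ]
        klasses = [t.klass for t in near]
        design, matrix, t_peaks, _ = _simulate_probe(
            cap,
            rng,
            probe_id=gene.gene_id,
            chrom=gene.chrom,
            probe_pos=gene.tss,
            peak_classes=klasses,
            peak_intervals=spans,
        )
        designs[gene.gene_id] = design
        matrices[gene.gene_id] = matrix
        out_truths.extend(t_peaks)
    return designs, matrices, out_truths


# ---------------------------------------------------------------------------
# DE, ATAC, spike-in tables
# ---------------------------------------------------------------------------

def simulate_de_table(
    config: SimConfig,
    gene_labels: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """DE table (gene_id, log2fc, fdr, mean_expression) + true status map.

    KEE genes go down with ``p_down_kee``, others with ``p_down_nonkee``;
    non-down genes go up with ``p_up``.  FDR is drawn consistent with status
    (< 0.05 iff changed) and mean expression is shifted up for KEE genes.
    """
    if rng is None:
        rng = substream(config.seed, "de")
    de = config.de
    rows = []
    status: dict[str, str] = {}
    for gid, label in gene_labels.items():
        p_down = de.p_down_kee if label == "KEE_gene" else de.p_down_nonkee
        u = rng.random()
        if u < p_down:
            st = "down"
            fc = -abs(rng.normal(de.log2fc_mean, de.log2fc_sd))
            fc = min(fc, -1e-6)
            fdr = rng.uniform(1e-4, 0.049)
        elif u < p_down + de.p_up:
            st = "up"
            fc = abs(rng.normal(de.log2fc_mean, de.log2fc_sd))
            fc = max(fc, 1e-6)
            fdr = rng.uniform(1e-4, 0.049)
        else:
            st = "insensitive"
            fc = rng.normal(0.0, 0.1)
            fdr = rng.uniform(0.051, 1.0)
        expr = rng.normal(de.expression_base, de.expression_sd)
        if label == "KEE_gene":
            expr += de.kee_expression_shift
        rows.append(
            {
                "gene_id": gid,
                "log2fc": fc,
                "fdr": fdr,
                "mean_expression": expr,
            }
        )
        status[gid] = st
    return pd.DataFrame(rows), status


def simulate_atac_table(
    config: SimConfig,
    truths: Sequence[TrueEnhancer],
    de_status: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ATAC peaks (chrom, start, end, direction, fdr).

    Decreased peaks are planted inside KEE/non-KEE enhancers whose assigned
    gene is down with the configured concordance probabilities; increased
    and unchanged peaks land in random enhancers.
    """
    if rng is None:
        rng = substream(config.seed, "atac")
    ac = config.atac

    def pool(klass: str, want_down: bool) -> list[TrueEnhancer]:
        return [
            t
            for t in truths
            if t.klass == klass
            and (de_status.get(t.gene_id) == "down") == want_down
        ]

    def peak_in(t: TrueEnhancer) -> tuple[str, int, int]:
        width = min(400, t.interval.length)
        lo = int(
            rng.integers(t.interval.start, max(t.interval.end - width, t.interval.start) + 1)
        )
        return t.interval.chrom, lo, lo + width

    rows = []
    for klass, n_dec, p_conc in (
        (KEE, ac.n_decreased_kee, ac.p_down_given_decreased_kee),
        (NONKEE, ac.n_decreased_nonkee, ac.p_down_given_decreased_nonkee),
    ):
        down_pool = pool(klass, True)
        other_pool = pool(klass, False)
        if not down_pool or not other_pool:
            raise ValueError(
                f"cannot plant decreased ATAC peaks: empty {klass} host pool"
            )
        for _ in range(n_dec):
            hosts = down_pool if rng.random() < p_conc else other_pool
            t = hosts[int(rng.integers(len(hosts)))]
            chrom, lo, hi = peak_in(t)
            rows.append(
                {
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "direction": "decreased",
                    "fdr": rng.uniform(1e-4, 0.049),
                }
            )
    for n, direction in ((ac.n_increased, "increased"), (ac.n_unchanged, "unchanged")):
        for _ in range(n):
            t = truths[int(rng.integers(len(truths)))]
            chrom, lo, hi = peak_in(t)
            fdr = (
                rng.uniform(1e-4, 0.049)
                if direction != "unchanged"
                else rng.uniform(0.051, 1.0)
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "direction": direction,
                    "fdr": fdr,
                }
            )
    return pd.DataFrame(rows)


def simulate_spikein(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, SpikeInCounts]:
    """Control and DOT1Li spike-in count rows.

    DOT1Li target-IP material is scaled by ``true_global_loss`` with spike
    material held fixed, then re-sequenced to the same depth; Poisson noise
    is applied unless ``noisy`` is off, in which case the rx factor ratio
    equals the loss exactly.
    """
    if rng is None:
        rng = substream(config.seed, "spikein")
    sp = config.spikein
    g = sp.true_global_loss
    if g <= 0:
        raise ValueError("true_global_loss must be > 0")

    def seq(target: float, spike: float) -> tuple[float, float]:
        depth = sp.n_target_ip + sp.n_spike_ip
        frac = target / (target + spike)
        t = depth * frac
        s = depth * (1 - frac)
        if sp.noisy:
            t, s = float(rng.poisson(t)), float(rng.poisson(s))
        return max(t, 1.0), max(s, 1.0)

    t_c, s_c = seq(sp.n_target_ip, sp.n_spike_ip)
    t_d, s_d = seq(sp.n_target_ip * g, sp.n_spike_ip)
    inp = (sp.n_target_input, sp.n_spike_input)
    if sp.noisy:
        inp = (
            max(float(rng.poisson(inp[0])), 1.0),
            max(float(rng.poisson(inp[1])), 1.0),
        )
    return {
        CONTROL: SpikeInCounts(t_c, s_c, inp[0], inp[1]),
        DOT1LI: SpikeInCounts(t_d, s_d, inp[0], inp[1]),
    }


# ---------------------------------------------------------------------------
# one-call simulation to disk
# ---------------------------------------------------------------------------

def run_simulation(config: SimConfig, outdir: str | Path) -> GroundTruthManifest:
    """Generate the full input bundle under ``outdir`` and write the manifest.

    Files: chrom.sizes, genes.tsv, peaks_<mark>.bed (4 marks),
    track_h3k79me2/me3.bedgraph (latent-correlated pair),
    track_h3k27ac_control/dot1li.bedgraph (KEE-attenuated pair),
    capture_design.tsv, capture_counts.tsv, de.tsv, atac.tsv, spikein.tsv,
    manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes, genes = simulate_genome_and_genes(config)
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, clen in sizes.items():
            fh.write(f"{chrom}\t{clen}\n")
    write_gene_table(genes, outdir / "genes.tsv")

    peaks, truths = simulate_enhancers_and_peaks(config, sizes, genes)
    for mark, ps in peaks.items():
        write_bed(list(ps), outdir / f"peaks_{mark.lower()}.bed")

    track_rng = substream(config.seed, "tracks")
    me2_track, me3_track = simulate_tracks(
        config, truths, sizes, rng=track_rng
    )
    write_bedgraph(me2_track, outdir / "track_h3k79me2.bedgraph", sizes)
    write_bedgraph(me3_track, outdir / "track_h3k79me3.bedgraph", sizes)
    ac_ctrl, ac_dot = simulate_tracks(
        config,
        truths,
        sizes,
        rng=track_rng,
        rho=1.0,
        attenuate_kee=config.capture.dot1li_effect,
    )
    write_bedgraph(ac_ctrl, outdir / "track_h3k27ac_control.bedgraph", sizes)
    write_bedgraph(ac_dot, outdir / "track_h3k27ac_dot1li.bedgraph", sizes)

    designs, matrices, capture_truths = simulate_capturec(config, genes, truths)
    write_capture_design(designs, outdir / "capture_design.tsv")
    write_fragment_counts(matrices, outdir / "capture_counts.tsv")
    peak_bed = [
        GenomicInterval(
            t.interval.chrom,
            t.interval.start,
            t.interval.end,
            name=f"{t.probe_id}:{t.klass}",
        )
        for t in capture_truths
    ]
    write_bed(peak_bed, outdir / "capture_peaks.bed")

    labels = true_gene_labels(truths, genes)
    de_df, de_status = simulate_de_table(config, labels)
    de_df.to_csv(outdir / "de.tsv", sep="\t", index=False)
    atac_df = simulate_atac_table(config, truths, de_status)
    atac_df.to_csv(outdir / "atac.tsv", sep="\t", index=False)
    write_spikein_table(simulate_spikein(config), outdir / "spikein.tsv")

    from .enhancer_classifier import mark_h3k79_genes

    manifest = GroundTruthManifest(
        config=config,
        enhancers=list(truths),
        gene_labels=labels,
        h3k79_marked=mark_h3k79_genes(genes, peaks["H3K79me2"]),
        de_status=de_status,
        capture_peaks=capture_truths,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def labels_from_manifest(
    manifest: GroundTruthManifest,
) -> list[GeneEnhancerLabel]:
    return [
        GeneEnhancerLabel(gid, label, manifest.h3k79_marked.get(gid, False))
        for gid, label in manifest.gene_labels.items()
    ]
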