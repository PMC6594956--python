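"""Differential Capture-C enhancer-promoter interaction testing.

Capture-C quantifies ligation frequency between a probed viewpoint (a gene
promoter) and the surrounding DpnII restriction fragments.  To test whether
DOT1L inhibition changes an enhancer-promoter interaction, per-fragment
counts are depth-normalized per replicate (reads per 100k cis-reported
reads), interaction peaks are filtered (cis to the probe, inside the
interaction domain, outside a 10 kb probe exclusion zone), and each retained
peak is tested with a paired Wilcoxon signed-rank over the normalized counts
of every overlapping fragment in every replicate, pairing replicate i of the
control condition with replicate i of the treated condition.  p-values are
Holm-Bonferroni adjusted within the retained peak family of each probe.

The signed-rank statistic follows classical conventions: zero differences
are dropped (reduced-sample), tied absolute differences get midranks, W is
the sum of positive ranks, and the two-sided p is exact (full permutation
distribution of sign assignments) for n <= 25 pairs, else a normal
approximation with tie correction and continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, interval_gap, overlaps

CONTROL = "control"
DOT1LI = "dot1li"

EXACT_THRESHOLD = 25  # largest n for exact signed-rank enumeration


@dataclass
class CaptureDesign:
    """One probe: hybridization site, interaction-domain bounds, replicates."""

    probe_id: str
    probe: GenomicInterval
    domain: GenomicInterval
    exclusion_radius: int = 10_000
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")
        if not (
            self.domain.chrom == self.probe.chrom
            and self.domain.start <= self.probe.start
            and self.probe.end <= self.domain.end
        ):
            raise ValueError(f"probe {self.probe_id} not inside its domain")


class FragmentCountMatrix:
    """Per-DpnII-fragment counts for replicates x {control, dot1li}.

    ``counts`` has shape (n_fragments, n_replicates, 2); condition axis order
    is (control, dot1li).  ``cis_totals`` (n_replicates, 2) defaults to the
    per-sample column sums and must dominate them.
    """

    def __init__(
        self,
        fragments: Sequence[GenomicInterval],
        counts: np.ndarray,
        cis_totals: np.ndarray | None = None,
    ):
        self.fragments = list(fragments)
        counts = np.asarray(counts)
        if counts.ndim != 3 or counts.shape[2] != 2:
            raise ValueError("counts must have shape (n_fragments, n_replicates, 2)")
        if counts.shape[0] != len(self.fragments):
            raise ValueError("counts row count does not match fragment count")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        for a, b in zip(self.fragments, self.fragments[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("fragments must be sorted and non-overlapping")
        self.counts = counts.astype(float)
        sums = self.counts.sum(axis=0)
        if cis_totals is None:
            cis_totals = sums
        cis_totals = np.asarray(cis_totals, dtype=float)
        if cis_totals.shape != counts.shape[1:]:
            raise ValueError("cis_totals must have shape (n_replicates, 2)")
        if np.any(cis_totals < sums - 1e-9):
            raise ValueError("cis_totals must be >= per-fragment sums")
        self.cis_totals = cis_totals

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]


def read_fragment_counts(
    path: str | Path,
) -> dict[str, FragmentCountMatrix]:
    """Read a fragment-counts TSV, one :class:`FragmentCountMatrix` per probe.

    Columns: probe_id, chrom, start, end, then one column per sample named
    ``control_<i>`` / ``dot1li_<i>`` with matching replicate indices.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    ctrl_cols = sorted(
        (c for c in df.columns if c.startswith(CONTROL + "_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    dot_cols = sorted(
        (c for c in df.columns if c.startswith(DOT1LI + "_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if len(ctrl_cols) != len(dot_cols) or not ctrl_cols:
        raise ValueError(
            f"{path}: unequal or missing replicate columns "
            f"({len(ctrl_cols)} control vs {len(dot_cols)} dot1li)"
        )
    out = {}
    for probe_id, sub in df.groupby("probe_id", sort=False):
        sub = sub.sort_values(["chrom", "start"])
        fragments = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sub.itertuples()
        ]
        counts = np.stack(
            [sub[ctrl_cols].to_numpy(), sub[dot_cols].to_numpy()], axis=2
        )
        out[str(probe_id)] = FragmentCountMatrix(fragments, counts)
    return out


def write_fragment_counts(
    matrices: dict[str, FragmentCountMatrix], path: str | Path
) -> None:
    rows = []
    for probe_id, m in matrices.items():
        for i, frag in enumerate(m.fragments):
            row = {
                "probe_id": probe_id,
                "chrom": frag.chrom,
                "start": frag.start,
                "end": frag.end,
            }
            for r in range(m.n_replicates):
                row[f"{CONTROL}_{r + 1}"] = m.counts[i, r, 0]
                row[f"{DOT1LI}_{r + 1}"] = m.counts[i, r, 1]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_capture_design(path: str | Path) -> dict[str, CaptureDesign]:
    """Design TSV columns: probe_id, chrom, start, end, domain_start, domain_end."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples():
        out[str(r.probe_id)] = CaptureDesign(
            probe_id=str(r.probe_id),
            probe=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            domain=GenomicInterval(r.chrom, int(r.domain_start), int(r.domain_end)),
            exclusion_radius=int(getattr(r, "exclusion_radius", 10_000)),
        )
    return out


def write_capture_design(
    designs: dict[str, CaptureDesign], path: str | Path
) -> None:
    rows = [
        {
            "probe_id": d.probe_id,
            "chrom": d.probe.chrom,
            "start": d.probe.start,
            "end": d.probe.end,
            "domain_start": d.domain.start,
            "domain_end": d.domain.end,
            "exclusion_radius": d.exclusion_radius,
        }
        for d in designs.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class InteractionPeakResult:
    """Signed-rank test result for one enhancer-promoter interaction peak."""

    peak: GenomicInterval
    enhancer_class: str = "unassigned"  # "KEE" | "nonKEE" | "unassigned"
    n_fragments: int = 0
    n_pairs: int = 0
    mean_control: float = 0.0
    mean_dot1li: float = 0.0
    mean_delta: float = 0.0
    statistic: float = 0.0
    p_raw: float = 1.0
    p_holm: float = 1.0


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def normalize_counts(matrix: FragmentCountMatrix) -> np.ndarray:
    """Reads per 100k cis-reported reads, per (replicate, condition)."""
    totals = matrix.cis_totals
    bad = np.argwhere(totals <= 0)
    if bad.size:
        r, k = bad[0]
        cond = (CONTROL, DOT1LI)[int(k)]
        raise ValueError(f"zero cis total for replicate {int(r) + 1} ({cond})")
    return matrix.counts * (100_000.0 / totals[None, :, :])


def filter_peaks(
    peaks: Sequence[GenomicInterval], design: CaptureDesign
) -> list[GenomicInterval]:
    """Keep peaks cis to the probe, fully inside the domain, and more than
    ``exclusion_radius`` bp (edge-to-edge) from the probe hybridization site."""
    kept = []
    for p in peaks:
        if p.chrom != design.probe.chrom:
            continue
        if p.start < design.domain.start or p.end > design.domain.end:
            continue
        if interval_gap(p, design.probe) <= design.exclusion_radius:
            continue
        kept.append(p)
    return kept


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p from the permutation distribution of W.

    ``ranks2`` are midranks doubled to integers; the distribution of
    2W = sum of a random subset of ranks2 is built by convolution (equivalent
    to enumerating all 2^n sign assignments).  All probabilities are dyadic
    rationals representable exactly in double precision for n <= 25.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = 0.5 * (dist + shifted)
    w2i = int(round(w2))
    p_le = float(dist[: w2i + 1].sum())
    p_ge = float(dist[w2i:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_signed_rank(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    exact_threshold: int = EXACT_THRESHOLD,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on (control, dot1li) pairs.

    Returns (W, two-sided p) with W the sum of positive ranks of the
    differences dot1li - control.  All-zero differences give (0, 1.0).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("paired_signed_rank requires at least one pair")
    d = arr[:, 1] - arr[:, 0]
    d = d[d != 0]  # reduced-sample convention
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks
    w = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        ranks2 = np.round(2 * ranks).astype(int)
        return w, _exact_signed_rank_p(ranks2, 2 * w)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if sigma2 <= 0:
        return w, 1.0
    z = w - mu
    z -= np.sign(z) * 0.5  # continuity correction
    p = 2.0 * stats.norm.sf(abs(z) / np.sqrt(sigma2))
    return w, min(1.0, float(p))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_peak(
    peak: GenomicInterval,
    matrix: FragmentCountMatrix,
    normalized: np.ndarray | None = None,
    exact_threshold: int = EXACT_THRESHOLD,
) -> InteractionPeakResult:
    """Signed-rank test of one peak over (fragment x replicate) pairs.

    Pairs replicate i of control with replicate i of dot1li for every
    fragment overlapping the peak.
    """
    if normalized is None:
        normalized = normalize_counts(matrix)
    idx = [i for i, f in enumerate(matrix.fragments) if overlaps(f, peak)]
    if not idx:
        raise ValueError(
            f"peak {peak.chrom}:{peak.start}-{peak.end} overlaps no fragment"
        )
    sub = normalized[idx]  # (n_frag, n_rep, 2)
    ctrl = sub[:, :, 0].ravel()
    dot = sub[:, :, 1].ravel()
    w, p = paired_signed_rank(
        np.column_stack([ctrl, dot]), exact_threshold=exact_threshold
    )
    delta = dot - ctrl
    return InteractionPeakResult(
        peak=peak,
        n_fragments=len(idx),
        n_pairs=int(np.sum(delta != 0)),
        mean_control=float(ctrl.mean()),
        mean_dot1li=float(dot.mean()),
        mean_delta=float(delta.mean()),
        statistic=w,
        p_raw=p,
    )


def differential_track(
    matrix: FragmentCountMatrix,
    window_fragments: int = 5,
    normalized: np.ndarray | None = None,
) -> list[tuple[GenomicInterval, float]]:
    """Per-fragment mean normalized (dot1li - control), smoothed by a sliding
    mean over ``window_fragments`` fragments (odd; truncated at the ends)."""
    if window_fragments < 1 or window_fragments % 2 == 0:
        raise ValueError("window_fragments must be a positive odd integer")
    if normalized is None:
        normalized = normalize_counts(matrix)
    delta = (normalized[:, :, 1] - normalized[:, :, 0]).mean(axis=1)
    smooth = (
        pd.Series(delta)
        .rolling(window_fragments, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return list(zip(matrix.fragments, smooth.tolist()))


def write_differential_track(
    track: Sequence[tuple[GenomicInterval, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for frag, value in track:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{value:g}\n")


def call_interaction_peaks(
    matrix: FragmentCountMatrix,
    quantile: float = 0.9,
    min_fragments: int = 3,
    smooth_window: int = 5,
    normalized: np.ndarray | None = None,
) -> list[GenomicInterval]:
    """Derive interaction peaks by thresholding the smoothed control mean.

    Runs of at least ``min_fragments`` consecutive fragments whose smoothed
    control-condition mean is at or above the q-th quantile become peaks.
    Provided because the study drew peak boundaries by eye; supplying peaks
    as a BED is the primary route.
    """
    if normalized is None:
        normalized = normalize_counts(matrix)
    ctrl = normalized[:, :, 0].mean(axis=1)
    smooth = (
        pd.Series(ctrl).rolling(smooth_window, center=True, min_periods=1).mean()
    ).to_numpy()
    thresh = np.quantile(smooth, quantile)
    above = smooth >= thresh
    peaks = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        if j - i + 1 >= min_fragments:
            peaks.append(
                GenomicInterval(
                    matrix.fragments[i].chrom,
                    matrix.fragments[i].start,
                    matrix.fragments[j].end,
                )
            )
        i = j + 1
    return peaks


def _attach_enhancer_class(
    result: InteractionPeakResult, enhancers
) -> InteractionPeakResult:
    # KEE takes precedence when a peak overlaps enhancers of both classes
    classes = {
        e.klass for e in enhancers if overlaps(result.peak, e.interval)
    }
    if "KEE" in classes:
        result.enhancer_class = "KEE"
    elif "nonKEE" in classes:
        result.enhancer_class = "nonKEE"
    return result


def run_capture_diff(
    design: CaptureDesign,
    matrix: FragmentCountMatrix,
    peaks: Sequence[GenomicInterval] | None = None,
    enhancers=None,
    window_fragments: int = 5,
    exact_threshold: int = EXACT_THRESHOLD,
) -> tuple[list[InteractionPeakResult], list[tuple[GenomicInterval, float]]]:
    """Full per-probe analysis: filter, test, Holm-adjust, differential track.

    The Holm family is the set of retained peaks of this probe.  When
    ``peaks`` is None they are derived with :func:`call_interaction_peaks`.
    ``enhancers`` (EnhancerCall collection) attaches KEE/non-KEE classes by
    >= 1 bp overlap.
    """
    normalized = normalize_counts(matrix)
    if peaks is None:
        peaks = call_interaction_peaks(matrix, normalized=normalized)
    retained = filter_peaks(peaks, design)
    results = [
        test_peak(p, matrix, normalized=normalized, exact_threshold=exact_threshold)
        for p in retained
    ]
    for r, adj in zip(results, holm_adjust([r.p_raw for r in results])):
        r.p_holm = float(adj)
    if enhancers is not None:
        results = [_attach_enhancer_class(r, enhancers) for r in results]
    track = differential_track(
        matrix, window_fragments=window_fragments, normalized=normalized
    )
    return results, track


def results_to_frame(
    results: Sequence[InteractionPeakResult], probe_id: str | None = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "chrom": r.peak.chrom,
            "start": r.peak.start,
            "end": r.peak.end,
            "enhancer_class": r.enhancer_class,
            "n_fragments": r.n_fragments,
            "n_pairs": r.n_pairs,
            "mean_control": r.mean_control,
            "mean_dot1li": r.mean_dot1li,
            "mean_delta": r.mean_delta,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_holm": r.p_holm,
        }
        if probe_id is not None:
            row = {"probe_id": probe_id, **row}
        rows.append(row)
    return pd.DataFrame(rows)
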