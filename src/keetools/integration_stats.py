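"""Cross-cutting statistics linking enhancer class to transcription and
chromatin accessibility.

Covers: mark-mark signal correlation at enhancers (Pearson on log2(x+1)
read sums by default), KEE vs non-KEE gene-expression comparison (two-sided
Wilcoxon rank-sum), differential-expression x enhancer-class contingency
tables with Fisher's exact test, the ATAC-direction x enhancer-class x
transcription cross-tabulation, and scaled-body metaprofiles.

Fisher's exact test is computed by exact rational enumeration of the
hypergeometric distribution over all tables with the observed margins,
summing the probabilities of tables no more probable than the observed one
(with the conventional tiny relative tolerance on the comparison, as used by
the standard R/scipy implementations).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enhancer_classifier import EnhancerCall, GeneEnhancerLabel
from .genomic_io import GeneModel, GenomicInterval, SignalTrack, nearest, overlaps

FDR_THRESHOLD = 0.05

UP = "up"
DOWN = "down"
INSENSITIVE = "insensitive"


@dataclass(frozen=True)
class DERecord:
    """Differential-expression call for one gene (treated vs control).

    ``status`` is determined by the FDR < 0.05 rule and the sign of log2fc;
    no fold-change floor is applied.
    """

    gene_id: str
    log2fc: float
    fdr: float

    @property
    def status(self) -> str:
        if self.fdr < FDR_THRESHOLD:
            if self.log2fc < 0:
                return DOWN
            if self.log2fc > 0:
                return UP
        return INSENSITIVE


@dataclass(frozen=True)
class AtacPeakRecord:
    interval: GenomicInterval
    direction: str  # "increased" | "decreased" | "unchanged"
    fdr: float

    def __post_init__(self) -> None:
        if self.direction not in ("increased", "decreased", "unchanged"):
            raise ValueError(f"bad ATAC direction {self.direction!r}")
        changed = self.direction != "unchanged"
        if changed != (self.fdr < FDR_THRESHOLD):
            raise ValueError(
                "ATAC direction inconsistent with FDR < 0.05 rule for "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


def read_de_table(path: str | Path) -> list[DERecord]:
    """TSV columns gene_id, log2fc, fdr (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    return [
        DERecord(str(r.gene_id), float(r.log2fc), float(r.fdr))
        for r in df.itertuples()
    ]


def read_atac_table(path: str | Path) -> list[AtacPeakRecord]:
    """TSV columns chrom, start, end, direction, fdr."""
    df = pd.read_csv(path, sep="\t")
    return [
        AtacPeakRecord(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            str(r.direction),
            float(r.fdr),
        )
        for r in df.itertuples()
    ]


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    cells: np.ndarray  # non-negative ints, shape (rows, cols)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if np.any(self.cells < 0):
            raise ValueError("contingency cells must be non-negative")
        if self.cells.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("cell shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=self.row_labels, columns=self.col_labels
        )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p).  The odds ratio is the sample OR a*d/(b*c),
    reported as inf when b*c == 0 (and a*d > 0) and nan when both products
    vanish.  The p-value sums exact hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if np.any(np.asarray(table) < 0):
        raise ValueError("cells must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    gate = p_obs * Fraction(10_000_001, 10_000_000)  # (1 + 1e-7) relative gate
    p = sum(pr for pr in probs.values() if pr <= gate)
    return odds, min(1.0, float(p))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, w2: int) -> float:
    """Exact two-sided p for the rank-sum W of group 1 (size n1) by DP.

    ``ranks2`` are combined midranks doubled to integers.  dp[k][s] counts
    subsets of size k with rank sum s; the null distribution of W follows by
    symmetry of the uniform random assignment.
    """
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n1, len(ranks2)), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n1]
    dist /= dist.sum()
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_group: int = 12,
    exact_max_total: int = 60,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact (midrank DP over all assignments) when the smaller group has at
    most ``exact_max_group`` members and the combined sample at most
    ``exact_max_total``; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    if min(n1, n2) <= exact_max_group and n1 + n2 <= exact_max_total:
        ranks2 = np.round(2 * ranks).astype(int)
        return _exact_rank_sum_p(ranks2, n1, int(round(2 * w)))
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / ((n) * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = w - mu
    z -= np.sign(z) * 0.5
    return min(1.0, 2.0 * float(stats.norm.sf(abs(z) / np.sqrt(sigma2))))


# ---------------------------------------------------------------------------
# signal correlation / metaprofiles
# ---------------------------------------------------------------------------

def _interval_signal(track: SignalTrack, iv: GenomicInterval) -> float:
    """Sum of overlapped bin values, partial bins pro-rated by overlap fraction."""
    w = track.bin_width
    lo = iv.start // w
    hi = -(-iv.end // w)
    arr = track.chrom_array(iv.chrom, hi)
    total = 0.0
    for b in range(lo, hi):
        bin_lo, bin_hi = b * w, (b + 1) * w
        frac = (min(iv.end, bin_hi) - max(iv.start, bin_lo)) / w
        total += float(arr[b]) * frac
    return total


def correlate_signal(
    track_a: SignalTrack,
    track_b: SignalTrack,
    intervals: Sequence[GenomicInterval],
    transform: str = "log2p1",
) -> tuple[pd.DataFrame, float]:
    """Per-interval paired signal sums and their Pearson correlation."""
    if track_a.bin_width != track_b.bin_width:
        raise ValueError("tracks must share a bin grid")
    if len(intervals) < 3:
        raise ValueError("need at least 3 intervals to correlate")
    if transform not in ("log2p1", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    a = np.array([_interval_signal(track_a, iv) for iv in intervals])
    b = np.array([_interval_signal(track_b, iv) for iv in intervals])
    if transform == "log2p1":
        a, b = np.log2(a + 1), np.log2(b + 1)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in interval signal; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "signal_a": a,
            "signal_b": b,
        }
    )
    return df, r


def metaprofile(
    track: SignalTrack,
    intervals: Sequence[GenomicInterval],
    flank_bp: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> tuple[np.ndarray, int]:
    """Scaled-body mean signal profile across an interval set.

    Each interval body is rescaled to ``n_body_bins`` positions by linear
    interpolation of the per-track-bin signal; flanks are fixed-bp windows
    of ``flank_bp / n_flank_bins`` each.  Returns (profile of length
    n_body_bins + 2*n_flank_bins, number of skipped short intervals).
    """
    if not intervals:
        raise ValueError("empty interval set")
    if n_body_bins < 1 or (n_flank_bins < 1 and flank_bp > 0):
        raise ValueError("bin counts must be >= 1")
    w = track.bin_width
    profiles = []
    skipped = 0
    for iv in intervals:
        if iv.length < w:
            skipped += 1
            continue
        lo_bin = iv.start // w
        hi_bin = -(-iv.end // w)
        arr = track.chrom_array(iv.chrom, hi_bin + (flank_bp // w) + 1)
        body_vals = arr[lo_bin:hi_bin]
        # body: interpolate the per-bin signal at n_body_bins even positions
        src_x = np.arange(len(body_vals), dtype=float)
        dst_x = np.linspace(0, len(body_vals) - 1, n_body_bins)
        body = np.interp(dst_x, src_x, body_vals)
        if flank_bp > 0:
            fw = flank_bp / n_flank_bins
            left = np.empty(n_flank_bins)
            right = np.empty(n_flank_bins)
            for i in range(n_flank_bins):
                l_lo = iv.start - flank_bp + i * fw
                left[i] = _window_mean(track, iv.chrom, l_lo, l_lo + fw)
                r_lo = iv.end + i * fw
                right[i] = _window_mean(track, iv.chrom, r_lo, r_lo + fw)
            profiles.append(np.concatenate([left, body, right]))
        else:
            profiles.append(body)
    if not profiles:
        raise ValueError("all intervals shorter than one track bin")
    return np.mean(profiles, axis=0), skipped


def _window_mean(track: SignalTrack, chrom: str, lo: float, hi: float) -> float:
    """Overlap-weighted mean bin signal over [lo, hi); out-of-range reads 0."""
    w = track.bin_width
    lo = max(0.0, lo)
    if hi <= lo:
        return 0.0
    b_lo = int(lo // w)
    b_hi = int(-(-hi // w))
    arr = track.chrom_array(chrom, b_hi)
    total = 0.0
    weight = 0.0
    for b in range(b_lo, b_hi):
        ov = min(hi, (b + 1) * w) - max(lo, b * w)
        if ov > 0:
            total += float(arr[b]) * ov
            weight += ov
    return total / weight if weight > 0 else 0.0


# ---------------------------------------------------------------------------
# class-level comparisons
# ---------------------------------------------------------------------------

def _label_map(labels: Sequence[GeneEnhancerLabel]) -> dict[str, GeneEnhancerLabel]:
    out: dict[str, GeneEnhancerLabel] = {}
    for lab in labels:
        if lab.gene_id in out:
            raise ValueError(f"duplicate gene_id {lab.gene_id!r} in labels")
        out[lab.gene_id] = lab
    return out


def compare_expression(
    labels: Sequence[GeneEnhancerLabel],
    expression: Mapping[str, float] | pd.DataFrame,
    restrict_to_h3k79_marked: bool = True,
) -> dict:
    """KEE-gene vs non-KEE-gene expression comparison (rank-sum test).

    ``expression`` maps gene_id -> expression value (e.g. log FPKM), or is a
    DataFrame with gene_id and expression columns.  Genes without gene-body
    H3K79 marking are excluded by default, since unmarked genes are generally
    lowly expressed and would bias the comparison.
    """
    if isinstance(expression, pd.DataFrame):
        col = "expression" if "expression" in expression else "mean_expression"
        expression = dict(
            zip(expression["gene_id"].astype(str), expression[col].astype(float))
        )
    lmap = _label_map(labels)
    groups: dict[str, list[float]] = {"KEE_gene": [], "nonKEE_gene": []}
    for gid, value in expression.items():
        lab = lmap.get(gid)
        if lab is None or lab.label not in groups:
            continue
        if restrict_to_h3k79_marked and not lab.h3k79_marked:
            continue
        groups[lab.label].append(float(value))
    kee, non = groups["KEE_gene"], groups["nonKEE_gene"]
    if not kee or not non:
        raise ValueError("one expression group is empty after restriction")
    return {
        "kee_values": np.asarray(kee),
        "nonkee_values": np.asarray(non),
        "kee_median": float(np.median(kee)),
        "nonkee_median": float(np.median(non)),
        "kee_iqr": tuple(np.percentile(kee, [25, 75])),
        "nonkee_iqr": tuple(np.percentile(non, [25, 75])),
        "p": rank_sum(kee, non),
    }


def de_by_class(
    labels: Sequence[GeneEnhancerLabel],
    de_records: Sequence[DERecord],
    restrict_to_h3k79_marked: bool = True,
) -> dict:
    """Class x DE-status contingency with collapsed down-vs-not Fisher test."""
    lmap = _label_map(labels)
    seen: set[str] = set()
    counts = {
        ("KEE_gene", s): 0 for s in (UP, DOWN, INSENSITIVE)
    } | {("nonKEE_gene", s): 0 for s in (UP, DOWN, INSENSITIVE)}
    fc_sums = {"KEE_gene": [], "nonKEE_gene": []}
    for rec in de_records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in DE table")
        seen.add(rec.gene_id)
        lab = lmap.get(rec.gene_id)
        if lab is None or lab.label == "none":
            continue
        if restrict_to_h3k79_marked and not lab.h3k79_marked:
            continue
        counts[(lab.label, rec.status)] += 1
        fc_sums[lab.label].append(rec.log2fc)
    classes = ["KEE_gene", "nonKEE_gene"]
    statuses = [UP, DOWN, INSENSITIVE]
    cells = np.array([[counts[(k, s)] for s in statuses] for k in classes])
    table = ContingencyTable(classes, statuses, cells)
    row_totals = cells.sum(axis=1)
    proportions = {
        k: {
            s: (counts[(k, s)] / row_totals[i] if row_totals[i] else math.nan)
            for s in statuses
        }
        for i, k in enumerate(classes)
    }
    down = cells[:, statuses.index(DOWN)]
    collapsed = ContingencyTable(
        classes, [DOWN, "not_down"], np.column_stack([down, row_totals - down])
    )
    odds, p = fisher_exact(collapsed.cells)
    mean_log2fc = {
        k: (float(np.mean(v)) if v else math.nan) for k, v in fc_sums.items()
    }
    return {
        "table": table,
        "collapsed": collapsed,
        "proportions": proportions,
        "mean_log2fc": mean_log2fc,
        "odds_ratio": odds,
        "p": p,
    }


def atac_cross_tab(
    atac: Sequence[AtacPeakRecord],
    enhancers: Sequence[EnhancerCall],
    labels: Sequence[GeneEnhancerLabel],
    de_records: Sequence[DERecord],
    genes: Sequence[GeneModel] | None = None,
) -> dict:
    """ATAC-direction x enhancer-class table, plus transcription outcome of
    decreased in-enhancer peaks, with Fisher's exact test on the collapsed
    down-vs-not 2x2.

    Each ATAC peak is assigned one class bucket: KEE if it overlaps any KEE
    enhancer (precedence), else nonKEE if it overlaps any non-KEE enhancer,
    else neither.  A peak's gene is the assigned gene of its containing
    enhancer, falling back to the nearest gene when ``genes`` is given.
    """
    status = {r.gene_id: r.status for r in de_records}
    by_chrom: dict[str, list[EnhancerCall]] = {}
    for e in enhancers:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    if genes is not None:
        for g in genes:
            gene_by_chrom.setdefault(g.chrom, []).append(g)

    directions = ["increased", "decreased", "unchanged"]
    classes = ["KEE", "nonKEE", "neither"]
    dir_cells = np.zeros((len(directions), len(classes)), dtype=int)
    statuses = [DOWN, UP, INSENSITIVE]
    dec_cells = np.zeros((2, len(statuses)), dtype=int)  # rows KEE, nonKEE

    for peak in atac:
        hits = [
            e
            for e in by_chrom.get(peak.interval.chrom, ())
            if overlaps(peak.interval, e.interval)
        ]
        if any(e.klass == "KEE" for e in hits):
            klass = "KEE"
            host = next(e for e in hits if e.klass == "KEE")
        elif hits:
            klass = "nonKEE"
            host = hits[0]
        else:
            klass = "neither"
            host = None
        dir_cells[directions.index(peak.direction), classes.index(klass)] += 1
        if peak.direction == "decreased" and klass in ("KEE", "nonKEE"):
            gid = host.gene_id if host is not None else None
            if gid is None and gene_by_chrom:
                cands = gene_by_chrom.get(peak.interval.chrom)
                if cands:
                    gid = nearest(peak.interval, cands)[0].gene_id
            st = status.get(gid, None)
            if st is not None:
                dec_cells[0 if klass == "KEE" else 1, statuses.index(st)] += 1

    direction_table = ContingencyTable(directions, classes, dir_cells)
    decreased_table = ContingencyTable(["KEE", "nonKEE"], statuses, dec_cells)
    row_totals = dec_cells.sum(axis=1)
    down_col = dec_cells[:, statuses.index(DOWN)]
    collapsed = ContingencyTable(
        ["KEE", "nonKEE"],
        [DOWN, "not_down"],
        np.column_stack([down_col, row_totals - down_col]),
    )
    odds, p = fisher_exact(collapsed.cells)
    proportions = {
        k: (down_col[i] / row_totals[i] if row_totals[i] else math.nan)
        for i, k in enumerate(["KEE", "nonKEE"])
    }
    return {
        "direction_table": direction_table,
        "decreased_table": decreased_table,
        "collapsed": collapsed,
        "down_proportions": proportions,
        "odds_ratio": odds,
        "p": p,
    }
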