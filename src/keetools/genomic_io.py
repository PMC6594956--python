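"""Genomic interval algebra and plain-text format I/O.

All coordinates are 0-based half-open (BED convention).  The types here —
:class:`GenomicInterval`, :class:`ChromSizes`, :class:`PeakSet`,
:class:`SignalTrack`, :class:`GeneModel` — are the substrate for every other
module: enhancer classification, spike-in normalization, Capture-C testing
and the integration statistics all operate on them.

Supported formats: BED3/BED6 and narrowPeak (read; columns beyond 6 dropped),
bedGraph on a fixed bin grid, two-column chrom.sizes, and a tab-separated
gene table with header ``gene_id  gene_name  chrom  start  end  strand``.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in a text genomic file (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class ChromSizes:
    """Chromosome name -> length (bp) mapping with uniqueness/positivity checks."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = sizes.items() if isinstance(sizes, Mapping) else list(sizes)
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._sizes[name] = length

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )


@dataclass
class PeakSet:
    """Peak calls for one histone mark, sorted by (chrom, start)."""

    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)

    def self_merge(self) -> "PeakSet":
        """Collapse overlapping/adjacent peaks of the same mark (gap 0)."""
        return PeakSet(self.mark, merge_intervals(self.intervals, max_gap=1))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


class SignalTrack:
    """Binned signal (e.g. tags per 10 million) on a fixed bp grid.

    Values are dense per-chromosome arrays starting at bin 0; any bin not
    covered by a record reads as 0.  Values must be >= 0 before differencing.
    """

    def __init__(self, bin_width: int, values: Mapping[str, np.ndarray] | None = None):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = int(bin_width)
        self.values: dict[str, np.ndarray] = {
            c: np.asarray(v, dtype=float) for c, v in (values or {}).items()
        }

    def get(self, chrom: str, bin_index: int) -> float:
        arr = self.values.get(chrom)
        if arr is None or bin_index < 0 or bin_index >= len(arr):
            return 0.0
        return float(arr[bin_index])

    def chrom_array(self, chrom: str, n_bins: int | None = None) -> np.ndarray:
        arr = self.values.get(chrom, np.zeros(0))
        if n_bins is None:
            return arr
        if len(arr) >= n_bins:
            return arr[:n_bins]
        return np.concatenate([arr, np.zeros(n_bins - len(arr))])

    def set_bin(self, chrom: str, bin_index: int, value: float) -> None:
        arr = self.values.get(chrom)
        if arr is None or bin_index >= len(arr):
            new = np.zeros(bin_index + 1)
            if arr is not None:
                new[: len(arr)] = arr
            self.values[chrom] = new
            arr = new
        arr[bin_index] = value

    def scaled(self, factor: float) -> "SignalTrack":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return SignalTrack(
            self.bin_width, {c: v * factor for c, v in self.values.items()}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.bin_width != other.bin_width:
            return False
        chroms = set(self.values) | set(other.values)
        for c in chroms:
            a = self.values.get(c, np.zeros(0))
            b = other.values.get(c, np.zeros(0))
            n = max(len(a), len(b))
            pa = np.concatenate([a, np.zeros(n - len(a))])
            pb = np.concatenate([b, np.zeros(n - len(b))])
            if not np.array_equal(pa, pb):
                return False
        return True


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its transcription start site implied by strand."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> ChromSizes:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name length'")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return ChromSizes(pairs)


def read_bed(
    path: str | Path, chrom_sizes: ChromSizes | None = None
) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak; columns beyond the sixth are ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 else ""
            try:
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {f[4]!r}") from exc
            strand = f[5] if len(f) > 5 else "."
            try:
                iv = GenomicInterval(f[0], start, end, strand, name, score)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if chrom_sizes is not None:
                chrom_sizes.validate(iv)
            out.append(iv)
    out.sort(key=GenomicInterval.sort_key)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED6; read_bed(write_bed(x)) round-trips the six columns."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            score = f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(
    path: str | Path, bin_width: int, chrom_sizes: ChromSizes | None = None
) -> SignalTrack:
    """Read a bedGraph whose records align to a fixed bin grid.

    Records may span several bins (uniform value across them); records that do
    not start/end on the grid raise a :class:`ParseError` naming the line.
    Missing bins read as 0.
    """
    track = SignalTrack(bin_width)
    buf: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 columns")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if start % bin_width != 0 or (
                end % bin_width != 0
                and not (chrom_sizes is not None and end == chrom_sizes[chrom])
            ):
                raise ParseError(
                    f"{path}:{lineno}: record {chrom}:{start}-{end} not aligned "
                    f"to {bin_width} bp grid"
                )
            for b in range(start // bin_width, -(-end // bin_width)):
                buf.setdefault(chrom, {})[b] = value
    for chrom, bins in buf.items():
        arr = np.zeros(max(bins) + 1)
        for b, v in bins.items():
            arr[b] = v
        track.values[chrom] = arr
    return track


def write_bedgraph(
    track: SignalTrack, path: str | Path, chrom_sizes: ChromSizes | None = None
) -> None:
    """Write non-zero bins; equal-valued adjacent bins are run-length merged."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            clen = chrom_sizes[chrom] if chrom_sizes is not None else None
            i = 0
            while i < len(arr):
                if arr[i] == 0.0:
                    i += 1
                    continue
                j = i
                while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                    j += 1
                end = (j + 1) * w
                if clen is not None:
                    end = min(end, clen)
                fh.write(f"{chrom}\t{i * w}\t{end}\t{arr[i]:g}\n")
                i = j + 1


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "gene_name", "chrom", "start", "end", "strand"]
        idx = {}
        for col in required:
            if col not in header:
                raise ParseError(f"{path}: missing column {col!r}")
            idx[col] = header.index(col)
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            gid = f[idx["gene_id"]]
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=f[idx["gene_name"]],
                    interval=GenomicInterval(
                        f[idx["chrom"]],
                        int(f[idx["start"]]),
                        int(f[idx["end"]]),
                        f[idx["strand"]],
                        name=gid,
                    ),
                )
            )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_name\tchrom\tstart\tend\tstrand\n")
        for g in sorted(genes, key=lambda g: g.interval.sort_key()):
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{g.gene_name}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int
) -> list[GenomicInterval]:
    """Merge intervals whose inter-interval gap is strictly below ``max_gap``.

    The gap between consecutive sorted intervals is ``next.start - prev.end``
    (overlapping intervals have gap <= 0 and always merge when max_gap >= 0).
    With ``max_gap=1000`` a 999 bp gap merges and a 1000 bp gap does not.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end < max_gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
        else:
            out.append(replace(iv, strand=".", name="", score=0.0))
    return out


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share >= 1 bp under half-open semantics."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """bp gap between closest edges on the same chromosome; 0 when overlapping."""
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes have no distance")
    return max(0, a.start - b.end, b.start - a.end)


def nearest(
    query: GenomicInterval,
    targets: Sequence[GeneModel] | Sequence[GenomicInterval],
    reference: str = "body",
) -> tuple:
    """Nearest target to ``query`` with signed distance.

    ``reference='body'`` measures edge-to-edge gap to the target interval
    (0 when overlapping); ``reference='tss'`` measures to the TSS point
    (GeneModel targets only).  Distance is negative when the target lies
    entirely left of the query.  Ties break toward smaller start, then
    lexicographic id.
    """
    if reference not in ("body", "tss"):
        raise ValueError(f"unknown reference {reference!r}")
    cands = []
    for t in targets:
        iv = t.interval if isinstance(t, GeneModel) else t
        if iv.chrom != query.chrom:
            continue
        if reference == "tss":
            if not isinstance(t, GeneModel):
                raise ValueError("tss reference requires GeneModel targets")
            p = t.tss
            if query.start <= p < query.end:
                d = 0
            elif p >= query.end:
                d = p - query.end + 1
            else:
                d = query.start - p
            signed = -d if p < query.start else d
        else:
            d = max(0, query.start - iv.end, iv.start - query.end)
            signed = -d if iv.end <= query.start else d
        ident = t.gene_id if isinstance(t, GeneModel) else iv.name
        cands.append((d, iv.start, ident, t, signed))
    if not cands:
        raise ValueError(
            f"no target on chromosome {query.chrom!r} for nearest() query"
        )
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    best = cands[0]
    return best[3], best[4]


def subtract_overlapping(
    intervals: Iterable[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop intervals overlapping any blacklist region (whole-interval filter).

    Used for optional excluded-region (e.g. blacklist) filtering of peak calls.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in sorted(blacklist, key=GenomicInterval.sort_key):
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    out = []
    for iv in intervals:
        hits = by_chrom.get(iv.chrom, [])
        starts = [s for s, _ in hits]
        i = bisect_left(starts, iv.end)
        if any(e > iv.start for _, e in hits[:i]):
            continue
        out.append(iv)
    return out
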