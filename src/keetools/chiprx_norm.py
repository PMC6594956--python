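"""Spike-in (ChIP-rx) normalization.

ChIP-rx adds a fixed ratio of cells from a second species (here Drosophila
spiked into human samples) before immunoprecipitation, so that the share of
reads mapping to the spike genome reports on global changes in the target
signal that depth normalization alone would hide.  The scale factor applied
to a tags-per-10-million track is the input-corrected spike ratio

    factor = (n_spike_input / n_target_input) / (n_spike_ip / n_target_ip)

i.e. the spike:target read ratio in the input sample over the same ratio in
the IP.  A global loss of target-genome IP signal inflates the spike share
of the IP and drives the factor below 1, deflating the track accordingly.
The exact formula used by the original pipeline is not published; this
input-corrected form is the standard ChIP-rx construction and is documented
as an interpretation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genomic_io import SignalTrack


@dataclass(frozen=True)
class SpikeInCounts:
    """Mapped read counts to target and spike genomes in IP and input samples."""

    n_target_ip: float
    n_spike_ip: float
    n_target_input: float
    n_spike_input: float

    def __post_init__(self) -> None:
        for name in (
            "n_target_ip",
            "n_spike_ip",
            "n_target_input",
            "n_spike_input",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RxFactor:
    """Dimensionless multiplicative factor for a tags-per-10-million track."""

    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("rx factor must be > 0")


def compute_rx_factor(counts: SpikeInCounts) -> RxFactor:
    """Input-corrected spike-ratio normalization factor (see module docstring)."""
    input_ratio = counts.n_spike_input / counts.n_target_input
    ip_ratio = counts.n_spike_ip / counts.n_target_ip
    return RxFactor(input_ratio / ip_ratio)


def scale_track(track: SignalTrack, factor: RxFactor | float) -> SignalTrack:
    """Multiply every bin by the rx factor; the bin grid is unchanged."""
    value = factor.value if isinstance(factor, RxFactor) else float(factor)
    if value <= 0:
        raise ValueError("scale factor must be > 0")
    return track.scaled(value)


def read_spikein_table(path: str | Path) -> dict[str, SpikeInCounts]:
    """Read a TSV of per-sample spike-in counts.

    Columns: sample, n_target_ip, n_spike_ip, n_target_input, n_spike_input.
    """
    out: dict[str, SpikeInCounts] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = ["sample", "n_target_ip", "n_spike_ip", "n_target_input", "n_spike_input"]
        idx = {}
        for c in cols:
            if c not in header:
                raise ValueError(f"{path}: missing column {c!r}")
            idx[c] = header.index(c)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            sample = f[idx["sample"]]
            if sample in out:
                raise ValueError(f"{path}: duplicate sample {sample!r}")
            out[sample] = SpikeInCounts(
                n_target_ip=float(f[idx["n_target_ip"]]),
                n_spike_ip=float(f[idx["n_spike_ip"]]),
                n_target_input=float(f[idx["n_target_input"]]),
                n_spike_input=float(f[idx["n_spike_input"]]),
            )
    return out


def write_spikein_table(
    counts: dict[str, SpikeInCounts], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tn_target_ip\tn_spike_ip\tn_target_input\tn_spike_input\n")
        for sample, c in counts.items():
            fh.write(
                f"{sample}\t{c.n_target_ip:g}\t{c.n_spike_ip:g}"
                f"\t{c.n_target_input:g}\t{c.n_spike_input:g}\n"
            )
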