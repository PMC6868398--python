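"""Spike-in normalization of ChIP coverage.

Stages, in pipeline order: partition reads by genome of origin and filter them
(mapping quality, blacklist), estimate the spike-in ratio from the input
sample, derive the per-ChIP scaling factor from spike-in ChIP reads in
spike-in peak regions, scale the target raw coverage track, and remove
background by subtracting the mode of the binned value distribution (negative
values floored at zero). Also provides genome-wide z-scoring and a documented
input-normalization stand-in (mass-matched log2 ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from chipquant.core_intervals import (
    ChromSizes,
    GenomicInterval,
    _StabIndex,
    merge_intervals,
)
from chipquant.coverage import CoverageTrack
from chipquant.io_formats import AlignedRead, resolve_genome

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeInEstimate",
    "ScalingFactor",
    "partition_and_filter",
    "spikein_ratio",
    "scaling_factor",
    "count_reads_in_peaks",
    "scale_track",
    "subtract_mode",
    "zscore_track",
    "input_normalize",
    "estimate_mode",
    "coverage_from_reads",
]


@dataclass(frozen=True)
class SpikeInEstimate:
    """Spike-in ratio r = spike-in reads / target reads in the input sample."""

    ratio: float
    n_spike: int
    n_target: int

    def __post_init__(self) -> None:
        if self.n_target <= 0:
            raise ValueError("n_target must be > 0")
        if not math.isclose(self.ratio, self.n_spike / self.n_target):
            raise ValueError("ratio must equal n_spike / n_target")


@dataclass(frozen=True)
class ScalingFactor:
    """Per-ChIP scaling factor s = r / (spike-in ChIP reads in peaks / 1e6)."""

    value: float
    source_ratio: SpikeInEstimate
    spike_reads_in_peaks: int

    def __post_init__(self) -> None:
        if self.spike_reads_in_peaks <= 0:
            raise ValueError("spike_reads_in_peaks must be > 0")
        expected = self.source_ratio.ratio / (self.spike_reads_in_peaks / 1e6)
        if not math.isclose(self.value, expected):
            raise ValueError("value must equal ratio / (reads_in_peaks / 1e6)")


def partition_and_filter(
    reads: Sequence[AlignedRead],
    mapq_min: int = 10,
    blacklist: Iterable[GenomicInterval] = (),
    genome_map: Mapping[str, str] | None = None,
) -> Tuple[Dict[str, List[AlignedRead]], Dict[str, int]]:
    """Split reads by genome label, keeping mapq >= mapq_min, non-blacklisted.

    A read overlapping any blacklist interval by >= 1 bp is dropped. When
    ``genome_map`` is given, each read's label is (re)resolved from its
    chromosome-name prefix; a chromosome matching no prefix is a hard error.
    Returns (per-genome read lists, per-genome kept counts).
    """
    index = _StabIndex.build(blacklist)
    by_genome: Dict[str, List[AlignedRead]] = {}
    for read in reads:
        if genome_map is not None:
            label = resolve_genome(read.interval.chrom, genome_map)
        else:
            label = read.genome
        if read.mapq < mapq_min:
            continue
        if index.overlaps_any(read.interval):
            continue
        by_genome.setdefault(label, []).append(read)
    counts = {g: len(lst) for g, lst in by_genome.items()}
    return by_genome, counts


def spikein_ratio(
    input_reads_by_genome: Mapping[str, Sequence[AlignedRead] | int],
    spike_label: str = "spike",
    target_label: str = "target",
) -> SpikeInEstimate:
    """Spike-in ratio from the INPUT sample: spike reads / target reads.

    Accepts either read lists or pre-computed counts per genome label.
    """

    def _count(x) -> int:
        return x if isinstance(x, int) else len(x)

    n_spike = _count(input_reads_by_genome.get(spike_label, 0))
    n_target = _count(input_reads_by_genome.get(target_label, 0))
    if n_target <= 0:
        raise ValueError("zero target reads in input sample; cannot form ratio")
    return SpikeInEstimate(ratio=n_spike / n_target, n_spike=n_spike, n_target=n_target)


def count_reads_in_peaks(
    reads: Sequence[AlignedRead], peaks: Iterable[GenomicInterval]
) -> int:
    """Number of reads overlapping >= 1 bp of any peak; each read counted once.

    Peaks are merged first so a read spanning two adjacent peaks still counts
    once.
    """
    index = _StabIndex.build(peaks)
    return sum(1 for r in reads if index.overlaps_any(r.interval))


def scaling_factor(
    est: SpikeInEstimate, chip_spike_reads_in_peaks: int
) -> ScalingFactor:
    """s = r / (spike-in ChIP reads in spike-in peak regions, in millions)."""
    if chip_spike_reads_in_peaks <= 0:
        raise ValueError("chip_spike_reads_in_peaks must be > 0")
    value = est.ratio / (chip_spike_reads_in_peaks / 1e6)
    return ScalingFactor(
        value=value, source_ratio=est, spike_reads_in_peaks=chip_spike_reads_in_peaks
    )


def scale_track(track: CoverageTrack, s: ScalingFactor) -> CoverageTrack:
    """Multiply every bin of a raw track by s.value; state becomes 'scaled'."""
    if track.state != "raw":
        raise ValueError(f"scale_track requires a raw track, got {track.state!r}")
    out = track.copy(state="scaled")
    for arr in out.data.values():
        arr *= s.value
    out.meta["scaling_factor"] = s.value
    return out


def estimate_mode(values: np.ndarray) -> float:
    """Mode of a (possibly continuous) value distribution.

    Freedman-Diaconis histogram over the value range; mode = midpoint of the
    tallest bin, ties broken toward the lower bin. When the FD width is
    degenerate (IQR = 0 or all values equal) the exact most-common value is
    returned (ties toward the smaller value).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate mode of empty array")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = values.min(), values.max()
    fd_width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    if iqr == 0.0 or fd_width <= 0.0 or lo == hi:
        uniq, counts = np.unique(values, return_counts=True)
        return float(uniq[np.argmax(counts)])  # argmax takes first (smallest) tie
    n_bins = max(1, int(math.ceil((hi - lo) / fd_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    k = int(np.argmax(counts))  # first max = lower bin on ties
    return float((edges[k] + edges[k + 1]) / 2.0)


def subtract_mode(track: CoverageTrack) -> CoverageTrack:
    """Remove background: subtract the mode of all bin values, floor at zero."""
    if track.state != "scaled":
        raise ValueError(f"subtract_mode requires a scaled track, got {track.state!r}")
    values = track.all_values()
    if not np.any(values):
        logger.warning("subtract_mode: all-zero track, returned unchanged")
        out = track.copy(state="background_subtracted")
        out.meta["mode"] = 0.0
        return out
    mode = estimate_mode(values)
    out = track.copy(state="background_subtracted")
    for chrom in out.data:
        out.data[chrom] = np.maximum(out.data[chrom] - mode, 0.0)
    out.meta["mode"] = mode
    logger.info("subtract_mode: estimated mode %.6g", mode)
    return out


def zscore_track(track: CoverageTrack) -> CoverageTrack:
    """(value - mean) / sd over all bins genome-wide; population sd."""
    values = track.all_values()
    mean = float(values.mean())
    sd = float(values.std())  # population (ddof=0)
    if sd == 0.0:
        raise ValueError("zscore_track: zero variance track")
    out = track.copy(state="zscored")
    for chrom in out.data:
        out.data[chrom] = (out.data[chrom] - mean) / sd
    out.meta.update(zscore_mean=mean, zscore_sd=sd)
    return out


def input_normalize(
    chip: CoverageTrack, input_track: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Stand-in for external input normalization: mass-matched log2 ratio.

    Both tracks are scaled to equal total mass, then per bin
    log2((chip + pseudocount) / (input + pseudocount)).
    """
    if not chip.compatible_with(input_track):
        raise ValueError("input_normalize: binning/chromosome mismatch")
    chip_mass = chip.total_mass()
    input_mass = input_track.total_mass()
    if chip_mass <= 0 or input_mass <= 0:
        raise ValueError("input_normalize: zero-mass track")
    target_mass = (chip_mass + input_mass) / 2.0
    out = chip.copy(state="input_normalized")
    for chrom in out.data:
        c = chip.data[chrom] * (target_mass / chip_mass)
        i = input_track.data[chrom] * (target_mass / input_mass)
        out.data[chrom] = np.log2((c + pseudocount) / (i + pseudocount))
    out.meta["pseudocount"] = pseudocount
    return out


def coverage_from_reads(
    reads: Sequence[AlignedRead], sizes: ChromSizes, bin: int = 10
) -> CoverageTrack:
    """Per-base read coverage resampled to fixed bins (mean depth per bin).

    Reads on chromosomes absent from ``sizes`` are ignored (e.g. spike-in reads
    when building the target-genome track).
    """
    track = CoverageTrack.zeros(sizes, bin)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for read in reads:
        iv = read.interval
        if iv.chrom in sizes:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, min(iv.end, sizes[iv.chrom])))
    for chrom, spans in by_chrom.items():
        chrom_len = sizes[chrom]
        spans_arr = np.asarray(spans, dtype=np.int64)
        # difference-array per-base depth, then mean per bin
        diff = np.zeros(chrom_len + 1, dtype=np.float64)
        np.add.at(diff, spans_arr[:, 0], 1.0)
        np.add.at(diff, spans_arr[:, 1], -1.0)
        depth = np.cumsum(diff[:-1])
        n_bins = len(track.data[chrom])
        padded = np.zeros(n_bins * bin, dtype=np.float64)
        padded[:chrom_len] = depth
        track.data[chrom] = padded.reshape(n_bins, bin).mean(axis=1)
    return track
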