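"""Interval algebra on 0-based, half-open genomic coordinates.

All region arithmetic in the package goes through this module. Coordinates follow
the BED convention: ``start`` is 0-based inclusive, ``end`` is exclusive, so an
interval covers the base positions ``start .. end-1`` and two intervals that merely
touch (``a.end == b.start``) share no base and do not overlap.

Strand is deliberately absent from :class:`GenomicInterval`; only gene starts
(promoter assignment) are strand-aware, and those live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "Peak",
    "overlaps",
    "intersect",
    "rescale_to_width",
    "merge_intervals",
    "sort_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span ``[start, end)`` on a named chromosome.

    Invariants: ``0 <= start < end`` and ``chrom`` non-empty; enforced at
    construction.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """floor((start + end) / 2) — deterministic for even widths."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end})"


class ChromSizes:
    """Mapping of chromosome name to length in bp (all lengths > 0)."""

    def __init__(self, sizes: Mapping[str, int]):
        clean: Dict[str, int] = {}
        for chrom, length in sizes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            clean[str(chrom)] = length
        self._sizes = clean

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ChromSizes):
            return self._sizes == other._sizes
        return NotImplemented

    def items(self):
        return self._sizes.items()

    def as_dict(self) -> Dict[str, int]:
        return dict(self._sizes)

    def validate_interval(self, iv: GenomicInterval) -> None:
        """Raise if ``iv`` is not fully inside its chromosome."""
        if iv.chrom not in self._sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds chromosome length {self._sizes[iv.chrom]}"
            )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus the absolute 0-based summit position.

    narrowPeak summit *offsets* are converted to absolute positions on read;
    this type only ever holds absolute coordinates.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval {self.interval}"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base (half-open convention)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def intersect(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """The maximal shared span of ``a`` and ``b``, or ``None`` when disjoint."""
    if not overlaps(a, b):
        return None
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def rescale_to_width(
    iv: GenomicInterval, width: int, sizes: ChromSizes
) -> GenomicInterval:
    """Return a ``width``-bp interval centered on the midpoint of ``iv``.

    The window is centered on ``floor((start+end)/2)``; if it would cross a
    chromosome boundary it is shifted (never truncated) to fit, preserving the
    exact width. A chromosome shorter than ``width`` is a hard error.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if iv.chrom not in sizes:
        raise KeyError(f"unknown chromosome {iv.chrom!r}")
    chrom_len = sizes[iv.chrom]
    if chrom_len < width:
        raise ValueError(
            f"chromosome {iv.chrom!r} (length {chrom_len}) is shorter than "
            f"requested width {width}"
        )
    start = iv.midpoint - width // 2
    if start < 0:
        start = 0
    elif start + width > chrom_len:
        start = chrom_len - width
    return GenomicInterval(iv.chrom, start, start + width)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Deterministic (chrom, start, end) ordering used for all outputs."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping intervals into maximal disjoint spans.

    Touching intervals (end == start) are NOT merged: under the half-open
    convention they share no base. Output is coordinate-sorted.
    """
    ivs = sort_intervals(intervals)
    merged: List[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class _StabIndex:
    """Sorted-array interval stabbing over a *merged, disjoint* interval set.

    Used for read/blacklist overlap queries; equivalent to an interval tree for
    disjoint inputs but with numpy-friendly arrays.
    """

    starts: Dict[str, List[int]] = field(default_factory=dict)
    ends: Dict[str, List[int]] = field(default_factory=dict)

    @classmethod
    def build(cls, intervals: Iterable[GenomicInterval]) -> "_StabIndex":
        idx = cls()
        for iv in merge_intervals(intervals):
            idx.starts.setdefault(iv.chrom, []).append(iv.start)
            idx.ends.setdefault(iv.chrom, []).append(iv.end)
        return idx

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        import bisect

        starts = self.starts.get(iv.chrom)
        if not starts:
            return False
        # candidate: rightmost stored interval starting before iv.end
        pos = bisect.bisect_left(starts, iv.end) - 1
        return pos >= 0 and self.ends[iv.chrom][pos] > iv.start
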