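"""Binned per-chromosome coverage tracks.

A :class:`CoverageTrack` stores one float array per chromosome at a fixed bin
size, plus a normalization-state tag that the pipeline stages check and advance
(raw -> scaled -> background_subtracted; z-scoring and input normalization
produce their own states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from chipquant.core_intervals import ChromSizes, GenomicInterval

__all__ = ["CoverageTrack", "TRACK_STATES"]

TRACK_STATES = ("raw", "scaled", "background_subtracted", "zscored", "input_normalized")

# states whose values must remain non-negative
_NONNEG_STATES = {"raw", "scaled", "background_subtracted"}


@dataclass
class CoverageTrack:
    """Fixed-bin numeric signal per chromosome.

    ``data[chrom]`` has length ``ceil(chrom_length / bin)``; the final bin may
    represent fewer than ``bin`` bases.
    """

    data: Dict[str, np.ndarray]
    bin: int
    sizes: ChromSizes
    state: str = "raw"
    meta: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin <= 0:
            raise ValueError("bin size must be positive")
        if self.state not in TRACK_STATES:
            raise ValueError(f"unknown track state {self.state!r}")
        for chrom, arr in self.data.items():
            expected = -(-self.sizes[chrom] // self.bin)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: array length {len(arr)} != ceil(len/bin) = {expected}"
                )
        if self.state in _NONNEG_STATES:
            for chrom, arr in self.data.items():
                if np.any(arr < 0):
                    raise ValueError(
                        f"negative values in {self.state!r} track on {chrom}"
                    )

    @classmethod
    def zeros(cls, sizes: ChromSizes, bin: int, state: str = "raw") -> "CoverageTrack":
        data = {
            chrom: np.zeros(-(-length // bin), dtype=float)
            for chrom, length in sizes.items()
        }
        return cls(data=data, bin=bin, sizes=sizes, state=state)

    def copy(self, state: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            data={c: a.copy() for c, a in self.data.items()},
            bin=self.bin,
            sizes=self.sizes,
            state=state or self.state,
            meta=dict(self.meta),
        )

    def all_values(self) -> np.ndarray:
        """All bin values genome-wide, concatenated in chromosome-name order."""
        return np.concatenate([self.data[c] for c in sorted(self.data)])

    def total_mass(self) -> float:
        """Sum of value x bin-width over all bins (last partial bin at full width)."""
        return float(sum(arr.sum() for arr in self.data.values()) * self.bin)

    def compatible_with(self, other: "CoverageTrack") -> bool:
        return (
            self.bin == other.bin
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )

    def values_in(self, iv: GenomicInterval) -> Tuple[np.ndarray, np.ndarray]:
        """(values, per-base weights) of the bins overlapping ``iv``.

        Weights are the number of bases of ``iv`` falling in each bin, so a
        weighted mean reproduces the exact per-base average.
        """
        arr = self.data[iv.chrom]
        b = self.bin
        first = iv.start // b
        last = (iv.end - 1) // b
        vals = arr[first : last + 1]
        weights = np.full(last - first + 1, b, dtype=float)
        weights[0] -= iv.start - first * b
        weights[-1] -= (last + 1) * b - iv.end
        if first == last:
            weights[0] = iv.width
        return vals, weights

    def mean_in(self, iv: GenomicInterval) -> float:
        """Exact per-base mean of the track signal over ``iv``."""
        vals, w = self.values_in(iv)
        return float(np.average(vals, weights=w))

    def window_profile(self, chrom: str, start: int, n_out: int, out_bin: int) -> Tuple[np.ndarray, bool]:
        """Length-weighted profile of ``n_out`` bins of ``out_bin`` bp from ``start``.

        ``start`` may be negative or the window may extend past the chromosome
        end; out-of-chromosome bases contribute 0 and the clipped flag is set.
        Requires ``out_bin`` to be a multiple of the track bin when they differ
        only by sampling granularity; arbitrary alignment is handled by exact
        per-base weighting of the underlying track bins.
        """
        arr = self.data[chrom]
        chrom_len = self.sizes[chrom]
        out = np.zeros(n_out, dtype=float)
        clipped = False
        b = self.bin
        for j in range(n_out):
            ws = start + j * out_bin
            we = ws + out_bin
            cs, ce = max(ws, 0), min(we, chrom_len)
            if cs >= ce:
                clipped = True
                continue
            if cs > ws or ce < we:
                clipped = True
            first = cs // b
            last = (ce - 1) // b
            total = 0.0
            for k in range(first, last + 1):
                lo = max(cs, k * b)
                hi = min(ce, (k + 1) * b)
                total += arr[k] * (hi - lo)
            out[j] = total / out_bin  # out-of-range bases count as 0 signal
        return out, clipped
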