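"""Independent brute-force oracles used across the test suite.

Every oracle here works by explicit enumeration over base positions, draws or
set elements, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, List, Optional, Set, Tuple

Interval = Tuple[str, int, int]  # (chrom, start, end), half-open


def base_set(iv: Interval) -> Set[Tuple[str, int]]:
    chrom, start, end = iv
    return {(chrom, pos) for pos in range(start, end)}


def overlaps_bp(a: Interval, b: Interval) -> bool:
    return bool(base_set(a) & base_set(b))


def intersect_bp(a: Interval, b: Interval) -> Optional[Interval]:
    shared = base_set(a) & base_set(b)
    if not shared:
        return None
    positions = sorted(pos for _, pos in shared)
    assert positions == list(range(positions[0], positions[-1] + 1))
    return (a[0], positions[0], positions[-1] + 1)


def union_components_bp(intervals: Iterable[Interval]) -> List[Interval]:
    """Connected overlap components as maximal runs of covered bases."""
    covered = set()
    for iv in intervals:
        covered |= base_set(iv)
    out = []
    by_chrom: dict = {}
    for chrom, pos in covered:
        by_chrom.setdefault(chrom, set()).add(pos)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        run_start = positions[0]
        prev = positions[0]
        for pos in positions[1:] + [None]:
            if pos is None or pos != prev + 1:
                out.append((chrom, run_start, prev + 1))
                run_start = pos
            prev = pos
    return out


def count_overlapping_reads_bp(
    reads: Iterable[Interval], peaks: Iterable[Interval]
) -> int:
    """O(n*m) per-read scan; each read counted at most once."""
    peaks = list(peaks)
    return sum(1 for r in reads if any(overlaps_bp(r, p) for p in peaks))


def hypergeom_tail_enum(
    universe: Set[str], set_a: Set[str], k_obs: int, draw_size: int
) -> float:
    """P(|draw ∩ A| >= k_obs) by full enumeration of all draws of draw_size."""
    total = 0
    hits = 0
    for draw in combinations(sorted(universe), draw_size):
        total += 1
        if len(set(draw) & set_a) >= k_obs:
            hits += 1
    return hits / total


def notch_oracle(values) -> Tuple[float, float]:
    """One-line-style independent Tukey notch computation."""
    import numpy as np

    v = np.sort(np.asarray(values, dtype=float))
    med = float(np.median(v))
    q1, q3 = float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75))
    half = 1.58 * (q3 - q1) / math.sqrt(len(v))
    return (med - half, med + half)
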