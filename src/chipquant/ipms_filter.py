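"""Spectral-count enrichment filter for AP-MS interactor lists.

A protein passes when, for at least one replicate, the IP spectral count meets
the minimum AND the matched control is either zero or out-ratioed. Setting
``min_ratio`` to infinity disables the ratio branch (control must be zero),
the stricter single-branch variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from chipquant.io_formats import SpectralCountRecord

__all__ = [
    "FilterParams",
    "passes_filter",
    "filter_table",
    "compare_baits",
]


@dataclass(frozen=True)
class FilterParams:
    min_sc: int = 3
    min_ratio: float = 5.0  # math.inf disables the ratio branch

    def __post_init__(self) -> None:
        if self.min_sc < 1:
            raise ValueError("min_sc must be >= 1")
        if not self.min_ratio > 0:
            raise ValueError("min_ratio must be > 0")


def _replicate_passes(ip: int, control: int, p: FilterParams) -> Tuple[bool, str]:
    """Evaluate one replicate; returns (verdict, branch in {none, zero, ratio})."""
    if ip < p.min_sc:
        return False, "none"
    if control == 0:
        return True, "zero"
    if math.isinf(p.min_ratio):
        return False, "none"
    # exact rational comparison: ip/control >= min_ratio
    if Fraction(ip, control) >= Fraction(p.min_ratio):
        return True, "ratio"
    return False, "none"


def passes_filter(rec: SpectralCountRecord, p: FilterParams) -> bool:
    """True iff some replicate i has sc_ip[i] >= min_sc and (control 0 or
    ip/control >= min_ratio). The whole conjunct is evaluated per replicate."""
    return any(
        _replicate_passes(ip, ctl, p)[0]
        for ip, ctl in zip(rec.sc_ip, rec.sc_control)
    )


def filter_table(
    records: Sequence[SpectralCountRecord], p: FilterParams
) -> Tuple[List[SpectralCountRecord], Dict]:
    """Order-preserving passing subset plus a report of thresholds and
    per-branch pass counts (a protein counts toward each branch that admits it
    in at least one replicate)."""
    passing: List[SpectralCountRecord] = []
    n_zero_branch = 0
    n_ratio_branch = 0
    for rec in records:
        branches = {
            _replicate_passes(ip, ctl, p)[1]
            for ip, ctl in zip(rec.sc_ip, rec.sc_control)
        }
        if branches & {"zero", "ratio"}:
            passing.append(rec)
            n_zero_branch += "zero" in branches
            n_ratio_branch += "ratio" in branches
    report = {
        "min_sc": p.min_sc,
        "min_ratio": None if math.isinf(p.min_ratio) else p.min_ratio,
        "n_input": len(records),
        "n_pass": len(passing),
        "n_pass_zero_control": n_zero_branch,
        "n_pass_ratio": n_ratio_branch,
    }
    return passing, report


def compare_baits(pass_sets: Mapping[str, Set[str]]) -> Dict:
    """Partition the union of per-bait interactor sets into: shared by all
    baits, unique to each bait, and (for >= 3 baits) a partially-shared rest."""
    if len(pass_sets) < 2:
        raise ValueError("compare_baits requires >= 2 baits")
    sets = {b: set(s) for b, s in pass_sets.items()}
    union: Set[str] = set().union(*sets.values())
    shared: Set[str] = set.intersection(*sets.values())
    unique = {
        bait: s - set().union(*(o for b, o in sets.items() if b != bait))
        for bait, s in sets.items()
    }
    partial = union - shared - set().union(*unique.values())
    return {
        "shared": shared,
        "unique": unique,
        "partial": partial,
        "counts": {
            "union": len(union),
            "shared": len(shared),
            **{f"unique_{b}": len(u) for b, u in unique.items()},
            "partial": len(partial),
        },
    }
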