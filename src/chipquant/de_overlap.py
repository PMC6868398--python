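"""Differential-expression list selection and exact overlap significance.

Universe = genes with baseMean strictly above the expression floor; up/down
sets per genotype at an adjusted-p threshold; overlap significance between two
gene lists by the exact upper hypergeometric tail (one-sided Fisher enrichment
test), computed by log-factorial summation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from chipquant.io_formats import DERecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEGeneSets",
    "select_universe",
    "de_sets",
    "overlap_test",
    "hypergeom_sf",
    "venn3_counts",
]


@dataclass(frozen=True)
class DEGeneSets:
    """Universe plus up/down gene sets for one genotype."""

    universe: FrozenSet[str]
    up: FrozenSet[str]
    down: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")
        if not (self.up <= self.universe and self.down <= self.universe):
            raise ValueError("up/down sets must be subsets of the universe")


def select_universe(
    records: Sequence[DERecord], basemean_min: float = 10.0
) -> Set[str]:
    """Genes with baseMean strictly greater than ``basemean_min``."""
    seen: Set[str] = set()
    out: Set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        if rec.base_mean > basemean_min:
            out.add(rec.gene_id)
    return out


def de_sets(
    records: Sequence[DERecord],
    universe: Set[str],
    alpha: float = 0.05,
) -> Tuple[Set[str], Set[str]]:
    """(up, down) gene sets: padj strictly < alpha, sign of log2fc.

    Records outside the universe are ignored; missing padj counts as not
    significant; log2fc == 0 with significant padj lands in neither set.
    """
    up: Set[str] = set()
    down: Set[str] = set()
    n_missing = 0
    n_zero_fc = 0
    for rec in records:
        if rec.gene_id not in universe:
            continue
        if rec.padj is None:
            n_missing += 1
            continue
        if rec.padj < alpha:
            if rec.log2fc > 0:
                up.add(rec.gene_id)
            elif rec.log2fc < 0:
                down.add(rec.gene_id)
            else:
                n_zero_fc += 1
    if n_missing:
        logger.info("de_sets: %d in-universe records with missing padj", n_missing)
    if n_zero_fc:
        logger.info("de_sets: %d significant records with log2fc == 0", n_zero_fc)
    return up, down


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_sf(k: int, population: int, successes: int, draws: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(population, successes, draws),
    by exact log-factorial summation."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("invalid hypergeometric margins")
    k_max = min(successes, draws)
    k_min_possible = max(0, successes + draws - population)
    if k <= k_min_possible:
        return 1.0
    if k > k_max:
        return 0.0
    denom = _log_comb(population, draws)
    total = 0.0
    for j in range(k, k_max + 1):
        total += math.exp(
            _log_comb(successes, j) + _log_comb(population - successes, draws - j) - denom
        )
    return min(total, 1.0)


def overlap_test(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> Tuple[int, float]:
    """Overlap count k = |A ∩ B| and one-sided enrichment p = P(X >= k)."""
    if not universe:
        raise ValueError("overlap_test: empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("overlap_test: sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = hypergeom_sf(k, len(universe), len(set_a), len(set_b))
    return k, p


def venn3_counts(a: Set[str], b: Set[str], c: Set[str]) -> Dict[str, int]:
    """The seven exclusive region counts of a three-set Venn diagram."""
    return {
        "abc": len(a & b & c),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "a": len(a - b - c),
        "b": len(b - a - c),
        "c": len(c - a - b),
    }
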