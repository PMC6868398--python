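"""Peak post-processing: summit extension, consensus, filtering, superset,
promoter assignment.

Every output region is exactly 300 bp (the configured width) wide: summit
extension produces fixed windows directly, and every intersection is rescaled
back to the fixed width, shift-to-fit at chromosome edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from chipquant.core_intervals import (
    ChromSizes,
    GenomicInterval,
    Peak,
    _StabIndex,
    intersect,
    merge_intervals,
    overlaps,
    rescale_to_width,
    sort_intervals,
)
from chipquant.coverage import CoverageTrack
from chipquant.io_formats import GeneAnnotation

__all__ = [
    "SupersetRegion",
    "PromoterAssignment",
    "extend_summits",
    "consensus",
    "antibody_consensus",
    "filter_peaks",
    "build_superset",
    "assign_promoters",
]


@dataclass(frozen=True)
class SupersetRegion:
    """A fixed-width region with boolean occupancy flags per factor."""

    interval: GenomicInterval
    flags: Mapping[str, bool]
    provenance: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not any(self.flags.values()):
            raise ValueError(f"superset region {self.interval} has no factor flag set")

    @property
    def factors(self) -> Tuple[str, ...]:
        return tuple(sorted(f for f, v in self.flags.items() if v))


@dataclass(frozen=True)
class PromoterAssignment:
    region: GenomicInterval
    gene_id: Optional[str]
    is_promoter: bool
    distance_to_start: Optional[int]  # signed; <0 gene start upstream of region


def extend_summits(
    peaks: Sequence[Peak], flank: int = 150, sizes: ChromSizes | None = None
) -> List[GenomicInterval]:
    """One ``2*flank``-bp window per summit, shift-to-fit at chromosome edges."""
    if sizes is None:
        raise ValueError("extend_summits requires chromosome sizes")
    out = []
    for p in peaks:
        # a 1-bp interval at the summit rescaled to the window width gives the
        # centered-and-shifted behavior for free
        point = GenomicInterval(p.interval.chrom, p.summit, p.summit + 1)
        out.append(rescale_to_width(point, 2 * flank, sizes))
    return out


def consensus(
    rep_a: Sequence[GenomicInterval],
    rep_b: Sequence[GenomicInterval],
    width: int = 300,
    sizes: ChromSizes | None = None,
) -> List[GenomicInterval]:
    """Confident calls: each overlapping cross-replicate pair's intersection,
    rescaled to ``width``, deduplicated, coordinate-sorted.

    A region of one input overlapping two of the other emits one consensus
    region per pair before deduplication.
    """
    if sizes is None:
        raise ValueError("consensus requires chromosome sizes")
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in rep_b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for lst in by_chrom.values():
        lst.sort(key=lambda iv: iv.start)
    out = set()
    for a in rep_a:
        for b in by_chrom.get(a.chrom, ()):
            if b.start >= a.end:
                break
            shared = intersect(a, b)
            if shared is not None:
                out.add(rescale_to_width(shared, width, sizes))
    return sort_intervals(out)


def antibody_consensus(
    calls_ab1: Sequence[GenomicInterval],
    calls_ab2: Sequence[GenomicInterval],
    width: int = 300,
    sizes: ChromSizes | None = None,
) -> List[GenomicInterval]:
    """Same operator as :func:`consensus`, applied across antibodies."""
    return consensus(calls_ab1, calls_ab2, width=width, sizes=sizes)


def filter_peaks(
    regions: Sequence[GenomicInterval],
    mappability: CoverageTrack | None = None,
    map_min_fraction: float = 0.25,
    blacklist: Iterable[GenomicInterval] = (),
) -> List[GenomicInterval]:
    """Discard regions overlapping a blacklist interval or any track bin with
    mappability below ``map_min_fraction``; survivors keep their order."""
    index = _StabIndex.build(blacklist)
    out = []
    for region in regions:
        if index.overlaps_any(region):
            continue
        if mappability is not None and region.chrom in mappability.data:
            vals, _ = mappability.values_in(region)
            if float(vals.min()) < map_min_fraction:
                continue
        out.append(region)
    return out


def build_superset(
    named_sets: Mapping[str, Sequence[GenomicInterval]],
    width: int = 300,
    sizes: ChromSizes | None = None,
    annotation_sets: Mapping[str, Sequence[GenomicInterval]] | None = None,
) -> List[SupersetRegion]:
    """Multi-factor superset: connected overlap components of the union of the
    building sets, one ``width``-bp representative per component.

    Components are maximal runs of >=1 bp-overlapping regions (single-factor
    regions form their own components and are kept). Each component's span is
    rescaled to ``width`` and annotated, by >=1 bp overlap of the rescaled
    region, against every factor's original regions — including
    ``annotation_sets`` factors that do not contribute components.
    """
    if sizes is None:
        raise ValueError("build_superset requires chromosome sizes")
    building = [iv for ivs in named_sets.values() for iv in ivs]
    components = merge_intervals(building)  # merged spans == connected components
    all_sets: Dict[str, Sequence[GenomicInterval]] = dict(named_sets)
    if annotation_sets:
        for name, ivs in annotation_sets.items():
            if name in all_sets:
                raise ValueError(f"factor {name!r} in both building and annotation sets")
            all_sets[name] = ivs
    indexes = {name: _StabIndex.build(ivs) for name, ivs in all_sets.items()}
    out = []
    for comp in components:
        region = rescale_to_width(comp, width, sizes)
        flags = {name: idx.overlaps_any(region) for name, idx in indexes.items()}
        provenance = tuple(
            iv
            for name in named_sets
            for iv in named_sets[name]
            if overlaps(iv, comp)
        )
        out.append(SupersetRegion(interval=region, flags=flags, provenance=provenance))
    return out


def _edge_distance(region: GenomicInterval, pos: int) -> int:
    """Signed edge-to-point distance; 0 when ``pos`` lies inside the region.

    Positive = gene start downstream of (right of) the region; the downstream
    distance is measured from the exclusive end coordinate, so [0,300) is at
    distance 500 from position 800.
    """
    if region.start <= pos < region.end:
        return 0
    if pos >= region.end:
        return pos - region.end
    return pos - region.start  # negative


def assign_promoters(
    regions: Sequence[GenomicInterval],
    promoter_annotation: Sequence[Tuple[GenomicInterval, str]] = (),
    genes: Sequence[GeneAnnotation] = (),
    max_dist: int = 500,
) -> List[PromoterAssignment]:
    """Assign regions to genes: annotated-promoter overlap first, then nearest
    gene start within ``max_dist`` bp (inclusive).

    Ties (equal |distance|) break by smallest distance then lexicographic
    gene id. Unassigned regions carry ``is_promoter=False``.
    """
    genes_by_chrom: Dict[str, List[GeneAnnotation]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for region in regions:
        assigned: Optional[Tuple[str, int]] = None
        for promoter_iv, gene_id in promoter_annotation:
            if overlaps(region, promoter_iv):
                assigned = (gene_id, _edge_distance(region, promoter_iv.midpoint))
                break
        if assigned is None:
            best: Optional[Tuple[int, str, int]] = None  # (|d|, gene_id, d)
            for g in genes_by_chrom.get(region.chrom, ()):
                d = _edge_distance(region, g.start)
                if abs(d) <= max_dist:
                    key = (abs(d), g.gene_id, d)
                    if best is None or key < best:
                        best = key
            if best is not None:
                assigned = (best[1], best[2])
        if assigned is None:
            out.append(PromoterAssignment(region, None, False, None))
        else:
            out.append(PromoterAssignment(region, assigned[0], True, assigned[1]))
    return out
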