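"""Region-level signal matrices, strong/weak k-means classes and notch-based
median comparison of region-set signal distributions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from chipquant.core_intervals import GenomicInterval
from chipquant.coverage import CoverageTrack

__all__ = [
    "RegionSignalMatrix",
    "StrongWeakClassification",
    "SetQuantification",
    "region_matrix",
    "kmeans_strong_weak",
    "quantify_sets",
    "notch_interval",
]

NOTCH_CONSTANT = 1.58  # Tukey/McGill: median +/- 1.58 * IQR / sqrt(n)


@dataclass
class RegionSignalMatrix:
    """Per-region binned signal over region +/- flank; rows follow region order."""

    values: np.ndarray  # (n_regions, n_bins)
    regions: List[GenomicInterval]
    track_id: str
    flank: int
    bin: int
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.regions):
            raise ValueError("matrix rows must match region list")
        if self.clipped is None:
            self.clipped = np.zeros(len(self.regions), dtype=bool)

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclass
class StrongWeakClassification:
    """strong/weak labels per region plus the fitted centroids and seed."""

    labels: List[str]  # "strong" | "weak", aligned with region order
    regions: List[GenomicInterval]
    centroids: Dict[str, np.ndarray]
    feature_names: List[str]
    seed: int

    def label_of(self, region: GenomicInterval) -> str:
        return self.labels[self.regions.index(region)]


@dataclass
class SetQuantification:
    """Per-region means for one region set plus Tukey summary."""

    name: str
    values: np.ndarray
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    notch: Optional[Tuple[float, float]]

    @property
    def empty(self) -> bool:
        return self.values.size == 0


def region_matrix(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    flank: int = 0,
    bin: int | None = None,
    track_id: str = "",
) -> RegionSignalMatrix:
    """Binned signal per region over ``[mid - w/2 - flank, mid + w/2 + flank)``.

    All regions must share one width ``w``. Bins default to the track bin;
    ``flank`` and the window width must be multiples of ``bin``.
    Out-of-chromosome bins read 0 and set the row's clipped flag.
    """
    if bin is None:
        bin = track.bin
    if not regions:
        return RegionSignalMatrix(
            np.zeros((0, 1)), [], track_id, flank, bin, np.zeros(0, dtype=bool)
        )
    widths = {iv.width for iv in regions}
    if len(widths) > 1:
        raise ValueError(f"regions must share one width, got {sorted(widths)}")
    width = widths.pop()
    if flank % bin or (width + 2 * flank) % bin:
        raise ValueError("flank and window width must be multiples of bin")
    half = width // 2 + flank
    n_bins = (width + 2 * flank) // bin
    values = np.zeros((len(regions), n_bins))
    clipped = np.zeros(len(regions), dtype=bool)
    for i, iv in enumerate(regions):
        values[i], clipped[i] = track.window_profile(
            iv.chrom, iv.midpoint - half, n_bins, bin
        )
    return RegionSignalMatrix(values, list(regions), track_id, flank, bin, clipped)


def kmeans_strong_weak(
    matrices: Mapping[str, RegionSignalMatrix],
    k: int = 2,
    seed: int = 13,
    n_init: int = 10,
    max_iter: int = 300,
    rank_by: str = "H3K4me3",
    tiebreak_by: str = "CFP-1",
    features: str = "mean",
) -> StrongWeakClassification:
    """Two-way k-means of per-region signal features; the cluster with the
    higher ``rank_by`` centroid (standardized space) is labelled "strong".

    ``matrices`` maps track name -> RegionSignalMatrix sharing region order.
    Default features: one standardized per-region mean per track;
    ``features="profile"`` clusters full standardized binned profiles instead.
    """
    if k != 2:
        raise ValueError("strong/weak classification is k = 2 by definition")
    names = list(matrices)
    if rank_by not in names:
        raise ValueError(f"rank_by track {rank_by!r} not among {names}")
    mats = [matrices[n] for n in names]
    regions = mats[0].regions
    if len(regions) < 2:
        raise ValueError("need >= 2 regions to cluster")
    for m in mats[1:]:
        if m.regions != regions:
            raise ValueError("matrices must share region order")
    if features == "mean":
        feat = np.column_stack([m.row_means() for m in mats])
        feature_names = names
        rank_cols = {n: [i] for i, n in enumerate(names)}
    elif features == "profile":
        feat = np.concatenate([m.values for m in mats], axis=1)
        feature_names = [
            f"{n}:{j}" for n, m in zip(names, mats) for j in range(m.values.shape[1])
        ]
        cols, rank_cols = 0, {}
        for n, m in zip(names, mats):
            rank_cols[n] = list(range(cols, cols + m.values.shape[1]))
            cols += m.values.shape[1]
    else:
        raise ValueError(f"unknown feature mode {features!r}")
    sd = feat.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate input: all regions identical on all features")
    sd = np.where(sd == 0, 1.0, sd)
    z = (feat - feat.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, random_state=seed, n_init=n_init, max_iter=max_iter)
    raw_labels = km.fit_predict(z)
    rank_score = km.cluster_centers_[:, rank_cols[rank_by]].mean(axis=1)
    if rank_score[0] == rank_score[1] and tiebreak_by in rank_cols:
        rank_score = km.cluster_centers_[:, rank_cols[tiebreak_by]].mean(axis=1)
    strong_cluster = int(np.argmax(rank_score))
    labels = ["strong" if l == strong_cluster else "weak" for l in raw_labels]
    centroids = {
        "strong": km.cluster_centers_[strong_cluster].copy(),
        "weak": km.cluster_centers_[1 - strong_cluster].copy(),
    }
    return StrongWeakClassification(
        labels=labels,
        regions=list(regions),
        centroids=centroids,
        feature_names=feature_names,
        seed=seed,
    )


def notch_interval(values: Sequence[float]) -> Tuple[float, float]:
    """Tukey notch: median +/- 1.58 * IQR / sqrt(n), type-7 quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("notch_interval requires n >= 1")
    median = float(np.median(arr))
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation (type 7)
    half = NOTCH_CONSTANT * (q3 - q1) / np.sqrt(arr.size)
    return (median - half, median + half)


def notches_overlap(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    """Closed-interval overlap; non-overlap is the 'significant' verdict."""
    return a[0] <= b[1] and b[0] <= a[1]


def quantify_sets(
    track: CoverageTrack,
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    require_zscored: bool = True,
) -> Dict[str, SetQuantification]:
    """Per-region mean signal for each named set, with Tukey summary.

    Empty sets are reported as empty quantifications, not errors.
    """
    if require_zscored and track.state != "zscored":
        raise ValueError(
            f"quantify_sets expects a z-scored track, got {track.state!r}"
        )
    out: Dict[str, SetQuantification] = {}
    for name, regions in region_sets.items():
        if not regions:
            out[name] = SetQuantification(name, np.array([]), None, None, None, None)
            continue
        means = np.array([track.mean_in(iv) for iv in regions])
        q1, q3 = np.percentile(means, [25, 75])
        out[name] = SetQuantification(
            name=name,
            values=means,
            median=float(np.median(means)),
            q1=float(q1),
            q3=float(q3),
            notch=notch_interval(means),
        )
    return out


__all__.append("notches_overlap")
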