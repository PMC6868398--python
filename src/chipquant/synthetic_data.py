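"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator draws from its own named substream of a single per-config seed,
so adding one generator never perturbs another's output at a fixed seed, and
every dataset ships with a machine-readable truth record.

Generators:

- two-genome read populations with a planted spike-in fraction (input + ChIP
  samples, planted peak regions in both genomes);
- multi-factor peak landscapes with controlled co-occupancy, replicate summit
  jitter and a bimodal strong/weak signal structure (plus simulated "mutant"
  tracks with reduced signal at strong sites);
- spectral-count tables with planted bait-specific interactors over a
  sub-threshold contaminant background;
- differential-expression tables for three genotypes with planted Venn overlap
  structure (or a null mode with independent gene draws).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from chipquant.core_intervals import ChromSizes, GenomicInterval, Peak
from chipquant.coverage import CoverageTrack
from chipquant.io_formats import AlignedRead, DERecord, GeneAnnotation, SpectralCountRecord

__all__ = [
    "SimConfig",
    "SpikeInSimulation",
    "LandscapeSimulation",
    "simulate_dual_genome_reads",
    "simulate_chip_sample",
    "simulate_peak_landscape",
    "simulate_sc_table",
    "simulate_de_tables",
]


@dataclass
class SimConfig:
    """All knobs for the generators; seeded runs are bit-reproducible."""

    seed: int = 0

    # genomes (target species gets the analysis; spike species only reads)
    target_chroms: Dict[str, int] = field(
        default_factory=lambda: {"ce_chrI": 1_000_000, "ce_chrII": 1_000_000}
    )
    spike_chroms: Dict[str, int] = field(default_factory=lambda: {"cb_chrI": 600_000})
    genome_map: Dict[str, str] = field(
        default_factory=lambda: {"ce_": "target", "cb_": "spike"}
    )

    # spike-in read simulation
    spike_ratio: float = 0.10
    n_input_reads: int = 100_000
    n_chip_reads: int = 200_000
    read_length: int = 50
    low_mapq_fraction: float = 0.05
    chip_peak_fraction: float = 0.8  # of each species' ChIP reads land in peaks
    n_target_peaks: int = 24
    n_spike_peaks: int = 12
    peak_flank: int = 150  # planted peaks are 2*flank wide

    # peak landscape
    n_sites: int = 400
    factors: Tuple[str, ...] = ("CFP-1", "SIN-3", "HDA-1")
    occupancy_probs: Dict[str, float] = field(
        default_factory=lambda: {"CFP-1": 0.75, "SIN-3": 0.5, "HDA-1": 0.5}
    )
    annotation_probs: Dict[str, float] = field(default_factory=lambda: {"MRG-1": 0.3})
    n_replicates: int = 2
    jitter_sd: float = 0.0
    strong_fraction: float = 0.4
    min_site_spacing: int = 700  # >= 600 so 300 bp regions merge only on purpose

    # analytic signal tracks
    bin: int = 10
    background: float = 1.0
    noise_sd: float = 0.05
    strong_amp: Dict[str, float] = field(
        default_factory=lambda: {"CFP-1": 8.0, "H3K4me3": 10.0, "SIN-3": 6.0, "HDA-1": 6.0}
    )
    weak_amp: Dict[str, float] = field(
        default_factory=lambda: {"CFP-1": 2.0, "H3K4me3": 1.5, "SIN-3": 6.0, "HDA-1": 6.0}
    )
    amp_sd: float = 0.4  # within-class per-site amplitude scatter
    mutant_strong_retention: float = 0.25  # strong-site signal kept in mutant
    mutant_tracks: Tuple[str, ...] = ("SIN-3", "HDA-1", "H3K4me3")

    # spectral-count table
    sc_n_proteins: int = 500
    sc_n_planted: int = 50
    sc_n_replicates: int = 2

    # differential-expression tables
    de_n_genes: int = 2_000
    de_basemean_fail_fraction: float = 0.1
    de_genotypes: Tuple[str, ...] = ("g1", "g2", "g3")
    # exclusive Venn cell counts, applied to both directions (up and down)
    de_venn: Dict[str, int] = field(
        default_factory=lambda: {
            "abc": 40, "ab": 20, "ac": 20, "bc": 20, "a": 60, "b": 60, "c": 60
        }
    )
    de_null: bool = False
    de_null_n_de: int = 150
    de_alpha: float = 0.05

    def rng(self, stream: str) -> np.random.Generator:
        """Independent named substream of this config's seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode("utf-8"))])

    @property
    def target_sizes(self) -> ChromSizes:
        return ChromSizes(self.target_chroms)

    @property
    def spike_sizes(self) -> ChromSizes:
        return ChromSizes(self.spike_chroms)

    @property
    def combined_sizes(self) -> ChromSizes:
        return ChromSizes({**self.target_chroms, **self.spike_chroms})


# ---------------------------------------------------------------------------
# helpers


def _uniform_positions(
    rng: np.random.Generator, chroms: Mapping[str, int], n: int, length: int
) -> List[Tuple[str, int]]:
    """n read start positions uniform over the concatenated genome."""
    names = sorted(chroms)
    spans = np.array([chroms[c] - length for c in names], dtype=np.int64)
    if np.any(spans <= 0):
        raise ValueError("chromosome shorter than read length")
    cum = np.concatenate([[0], np.cumsum(spans)])
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return [(names[i], int(u[j] - cum[i])) for j, i in enumerate(idx)]


def _plant_peaks(
    rng: np.random.Generator, chroms: Mapping[str, int], n: int, flank: int
) -> List[GenomicInterval]:
    """n non-overlapping 2*flank windows on an even grid with random offsets."""
    names = sorted(chroms)
    total = sum(chroms.values())
    spacing = total // n
    if spacing < 4 * flank:
        raise ValueError("too many peaks for genome size")
    peaks: List[GenomicInterval] = []
    placed = 0
    for name in names:
        n_here = round(n * chroms[name] / total)
        n_here = min(n_here, n - placed)
        for i in range(n_here):
            lo = i * (chroms[name] // max(n_here, 1)) + flank
            center = lo + int(rng.integers(0, flank))
            peaks.append(GenomicInterval(name, center - flank, center + flank))
        placed += n_here
    return peaks[:n]


def _make_reads(
    positions: Sequence[Tuple[str, int]],
    mapqs: np.ndarray,
    genome: str,
    length: int,
) -> List[AlignedRead]:
    return [
        AlignedRead(genome, GenomicInterval(chrom, pos, pos + length), int(q))
        for (chrom, pos), q in zip(positions, mapqs)
    ]


def _draw_mapq(rng: np.random.Generator, n: int, low_fraction: float) -> np.ndarray:
    low = rng.random(n) < low_fraction
    mapq = rng.integers(10, 61, size=n)
    mapq[low] = rng.integers(0, 10, size=int(low.sum()))
    return mapq


# ---------------------------------------------------------------------------
# dual-genome reads


@dataclass
class SpikeInSimulation:
    input_reads: List[AlignedRead]
    chip_reads: List[AlignedRead]
    target_peaks: List[GenomicInterval]
    spike_peaks: List[GenomicInterval]
    peak_weights: np.ndarray  # per-target-peak relative read weight
    truth: Dict


def _landscape_state(cfg: SimConfig):
    """Planted peaks and per-peak weights, shared by all samples of one config."""
    rng = cfg.rng("spikein-landscape")
    target_peaks = _plant_peaks(rng, cfg.target_chroms, cfg.n_target_peaks, cfg.peak_flank)
    spike_peaks = _plant_peaks(rng, cfg.spike_chroms, cfg.n_spike_peaks, cfg.peak_flank)
    weights = rng.lognormal(mean=0.0, sigma=0.25, size=len(target_peaks))
    weights /= weights.sum()
    return target_peaks, spike_peaks, weights


def simulate_chip_sample(
    cfg: SimConfig, n_reads: int, stream: str = "chip"
) -> List[AlignedRead]:
    """One ChIP sample over the planted landscape: per species, a fixed
    fraction of reads lands uniformly inside planted peak windows (peak chosen
    by its weight), the rest uniformly over the genome."""
    rng = cfg.rng(stream)
    target_peaks, spike_peaks, weights = _landscape_state(cfg)
    p_spike = cfg.spike_ratio / (1.0 + cfg.spike_ratio)
    n_spike = int(rng.binomial(n_reads, p_spike))
    n_target = n_reads - n_spike
    L = cfg.read_length
    reads: List[AlignedRead] = []
    for genome, chroms, peaks, w, n in (
        ("target", cfg.target_chroms, target_peaks, weights, n_target),
        ("spike", cfg.spike_chroms, spike_peaks, None, n_spike),
    ):
        n_peak = int(rng.binomial(n, cfg.chip_peak_fraction))
        if peaks and n_peak:
            idx = rng.choice(len(peaks), size=n_peak, p=w)
            offs = rng.integers(0, 2 * cfg.peak_flank - L, size=n_peak)
            pos = [(peaks[i].chrom, int(peaks[i].start + o)) for i, o in zip(idx, offs)]
        else:
            pos = []
        pos += _uniform_positions(rng, chroms, n - len(pos), L)
        reads.extend(_make_reads(pos, _draw_mapq(rng, n, cfg.low_mapq_fraction), genome, L))
    return reads


def simulate_dual_genome_reads(cfg: SimConfig) -> SpikeInSimulation:
    """Input and ChIP samples over a shared planted spike-in landscape.

    Input reads are species-assigned with probability r/(1+r) and placed
    uniformly; ChIP reads concentrate at the planted peaks.
    """
    rng = cfg.rng("input")
    target_peaks, spike_peaks, weights = _landscape_state(cfg)
    p_spike = cfg.spike_ratio / (1.0 + cfg.spike_ratio)
    n_spike = int(rng.binomial(cfg.n_input_reads, p_spike))
    n_target = cfg.n_input_reads - n_spike
    L = cfg.read_length
    input_reads = _make_reads(
        _uniform_positions(rng, cfg.target_chroms, n_target, L),
        _draw_mapq(rng, n_target, cfg.low_mapq_fraction),
        "target",
        L,
    ) + _make_reads(
        _uniform_positions(rng, cfg.spike_chroms, n_spike, L),
        _draw_mapq(rng, n_spike, cfg.low_mapq_fraction),
        "spike",
        L,
    )
    chip_reads = simulate_chip_sample(cfg, cfg.n_chip_reads, stream="chip")
    truth = {
        "spike_ratio": cfg.spike_ratio,
        "n_input_spike": n_spike,
        "n_input_target": n_target,
        "target_peaks": [[p.chrom, p.start, p.end] for p in target_peaks],
        "spike_peaks": [[p.chrom, p.start, p.end] for p in spike_peaks],
        "peak_weights": weights.tolist(),
    }
    return SpikeInSimulation(
        input_reads=input_reads,
        chip_reads=chip_reads,
        target_peaks=target_peaks,
        spike_peaks=spike_peaks,
        peak_weights=weights,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# peak landscape


@dataclass
class PlantedSite:
    chrom: str
    pos: int  # summit position
    site_class: str  # "strong" | "weak"
    flags: Dict[str, bool]

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos - 150, self.pos + 150)


@dataclass
class LandscapeSimulation:
    sites: List[PlantedSite]
    replicate_peaks: Dict[str, List[List[Peak]]]  # factor -> replicates -> peaks
    annotation_peaks: Dict[str, List[GenomicInterval]]  # e.g. MRG-1
    tracks: Dict[str, CoverageTrack]  # e.g. "CFP-1", "H3K4me3", "SIN-3_mut", ...
    genes: List[GeneAnnotation]
    sizes: ChromSizes
    truth: Dict


def simulate_peak_landscape(cfg: SimConfig) -> LandscapeSimulation:
    """Planted multi-factor landscape with strong/weak signal structure.

    Sites sit on a grid with spacing >= ``min_site_spacing`` (>= 600 bp, so
    300 bp regions from different sites can never merge by accident). Per-site
    factor flags are independent Bernoulli draws; sites with no factor at all
    are dropped. Each factor gets ``n_replicates`` peak call sets with summit
    jitter. Analytic tracks carry background + per-site boxcar amplitude +
    truncated-Gaussian noise; "mutant" variants retain only
    ``mutant_strong_retention`` of the amplitude at strong sites.
    """
    rng = cfg.rng("landscape")
    sizes = cfg.target_sizes
    names = sorted(cfg.target_chroms)
    capacity = sum((l - 400) // cfg.min_site_spacing for l in cfg.target_chroms.values())
    if cfg.n_sites > capacity:
        raise ValueError(
            f"cannot pack {cfg.n_sites} sites with spacing {cfg.min_site_spacing} "
            f"into genome of capacity {capacity}"
        )
    # grid positions, round-robin over chromosomes
    slots: List[Tuple[str, int]] = []
    for name in names:
        n_slots = (cfg.target_chroms[name] - 400) // cfg.min_site_spacing
        for i in range(n_slots):
            slots.append((name, 200 + i * cfg.min_site_spacing + cfg.min_site_spacing // 2))
    chosen = rng.choice(len(slots), size=cfg.n_sites, replace=False)
    chosen.sort()

    all_factors = list(cfg.factors) + list(cfg.annotation_probs)
    sites: List[PlantedSite] = []
    for slot in chosen:
        chrom, pos = slots[slot]
        flags = {f: bool(rng.random() < cfg.occupancy_probs.get(f, 0.0)) for f in cfg.factors}
        for f, p in cfg.annotation_probs.items():
            flags[f] = bool(rng.random() < p)
        if not any(flags[f] for f in cfg.factors):
            continue  # no building factor: no component would exist here
        site_class = "strong" if rng.random() < cfg.strong_fraction else "weak"
        sites.append(PlantedSite(chrom=chrom, pos=pos, site_class=site_class, flags=flags))

    # replicate peak calls with summit jitter
    replicate_peaks: Dict[str, List[List[Peak]]] = {}
    for factor in cfg.factors:
        reps: List[List[Peak]] = []
        for _ in range(cfg.n_replicates):
            peaks = []
            for site in sites:
                if not site.flags[factor]:
                    continue
                jitter = int(round(rng.normal(0.0, cfg.jitter_sd))) if cfg.jitter_sd else 0
                summit = min(max(site.pos + jitter, 150), sizes[site.chrom] - 150)
                amp = cfg.strong_amp if site.site_class == "strong" else cfg.weak_amp
                peaks.append(
                    Peak(
                        interval=GenomicInterval(site.chrom, summit - 150, summit + 150),
                        summit=summit,
                        score=amp.get(factor, 1.0),
                    )
                )
            peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
            reps.append(peaks)
        replicate_peaks[factor] = reps
    annotation_peaks = {
        f: [s.region for s in sites if s.flags[f]] for f in cfg.annotation_probs
    }

    # analytic signal tracks
    track_names = sorted(set(list(cfg.factors) + ["H3K4me3"]))
    tracks: Dict[str, CoverageTrack] = {}
    site_amps: Dict[str, np.ndarray] = {}
    for tname in track_names:
        amps = np.empty(len(sites))
        for i, site in enumerate(sites):
            base = (cfg.strong_amp if site.site_class == "strong" else cfg.weak_amp).get(
                tname, 0.0
            )
            amps[i] = max(base + rng.normal(0.0, cfg.amp_sd), 0.0)
        site_amps[tname] = amps
        for variant in ("", "_mut") if tname in cfg.mutant_tracks else ("",):
            track = CoverageTrack.zeros(sizes, cfg.bin)
            for chrom in track.data:
                noise = rng.normal(0.0, cfg.noise_sd, size=len(track.data[chrom]))
                track.data[chrom] = np.maximum(cfg.background + noise, 0.0)
            for i, site in enumerate(sites):
                has = site.flags.get(tname, tname == "H3K4me3")
                if not has:
                    continue
                amp = amps[i]
                if variant == "_mut" and site.site_class == "strong":
                    amp *= cfg.mutant_strong_retention
                arr = track.data[site.chrom]
                first = (site.pos - 150) // cfg.bin
                last = (site.pos + 150 - 1) // cfg.bin
                arr[first : last + 1] += amp
            tracks[tname + variant] = track

    # one gene per site: start 100 bp downstream of the summit, alternating strand
    genes = [
        GeneAnnotation(
            gene_id=f"gene_{i:05d}",
            chrom=site.chrom,
            start=site.pos + 100,
            strand="+" if i % 2 == 0 else "-",
        )
        for i, site in enumerate(sites)
    ]

    truth = {
        "sites": [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "class": s.site_class,
                "flags": s.flags,
                "region": [s.region.chrom, s.region.start, s.region.end],
            }
            for s in sites
        ],
        "strong_fraction_planted": cfg.strong_fraction,
        "jitter_sd": cfg.jitter_sd,
        "site_amplitudes": {t: a.tolist() for t, a in site_amps.items()},
    }
    return LandscapeSimulation(
        sites=sites,
        replicate_peaks=replicate_peaks,
        annotation_peaks=annotation_peaks,
        tracks=tracks,
        genes=genes,
        sizes=sizes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# spectral-count tables


def simulate_sc_table(cfg: SimConfig) -> Tuple[List[SpectralCountRecord], List[str]]:
    """SC table with planted true interactors over sub-threshold background.

    Planted proteins pass the default filter by construction (IP >= 3, control
    0 in at least one replicate); background proteins fail every replicate by
    construction (IP < 3, or a nonzero control with ratio < 5).
    """
    rng = cfg.rng("sc")
    planted_idx = set(
        rng.choice(cfg.sc_n_proteins, size=cfg.sc_n_planted, replace=False).tolist()
    )
    records: List[SpectralCountRecord] = []
    truth: List[str] = []
    for i in range(cfg.sc_n_proteins):
        pid = f"prot_{i:04d}"
        if i in planted_idx:
            hot = int(rng.integers(0, cfg.sc_n_replicates))
            sc_ip, sc_control = [], []
            for j in range(cfg.sc_n_replicates):
                if j == hot:
                    sc_ip.append(int(3 + rng.poisson(5)))
                    sc_control.append(0)
                else:
                    sc_ip.append(int(rng.poisson(4)))
                    sc_control.append(int(rng.poisson(1)))
            truth.append(pid)
        else:
            sc_ip, sc_control = [], []
            for _ in range(cfg.sc_n_replicates):
                if rng.random() < 0.7:
                    sc_ip.append(int(rng.integers(0, 3)))  # below min_sc
                    sc_control.append(int(rng.integers(0, 6)))
                else:
                    ip = int(rng.integers(4, 10))
                    sc_ip.append(ip)
                    sc_control.append(max(1, -(-ip // 4)))  # ratio <= 4 < 5
        records.append(
            SpectralCountRecord(pid, tuple(sc_ip), tuple(sc_control))
        )
    return records, truth


# ---------------------------------------------------------------------------
# differential-expression tables


def simulate_de_tables(
    cfg: SimConfig,
) -> Tuple[Dict[str, List[DERecord]], Dict]:
    """Three DE tables with planted Venn overlap structure per direction.

    Genes in a genotype's planted up/down set get padj < alpha with a matching
    fold-change sign; all other genes get padj >= alpha. A configurable
    fraction of genes fails the baseMean floor (drawn <= 10) and is never
    planted. In null mode each genotype instead draws its DE genes
    independently at random, with no overlap structure.
    """
    rng = cfg.rng("de")
    n = cfg.de_n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    n_fail = int(round(n * cfg.de_basemean_fail_fraction))
    fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist())
    expressed = [g for i, g in enumerate(genes) if i not in fail_idx]
    gt = list(cfg.de_genotypes)
    if len(gt) != 3:
        raise ValueError("simulate_de_tables expects exactly 3 genotypes")

    planted: Dict[str, Dict[str, set]] = {g: {"up": set(), "down": set()} for g in gt}
    if cfg.de_null:
        for g in gt:
            for direction in ("up", "down"):
                chosen = rng.choice(len(expressed), size=cfg.de_null_n_de, replace=False)
                planted[g][direction] = {expressed[i] for i in chosen}
        # up/down of one genotype must be disjoint: redraw overlaps to spares
        for g in gt:
            both = planted[g]["up"] & planted[g]["down"]
            planted[g]["down"] -= both
            spare = [x for x in expressed if x not in planted[g]["up"] | planted[g]["down"]]
            extra = rng.choice(len(spare), size=len(both), replace=False)
            planted[g]["down"] |= {spare[i] for i in extra}
        truth_venn = None
    else:
        cells = ("abc", "ab", "ac", "bc", "a", "b", "c")
        need = 2 * sum(cfg.de_venn.get(c, 0) for c in cells)
        if need > len(expressed):
            raise ValueError(
                f"infeasible Venn spec: needs {need} genes, only {len(expressed)} expressed"
            )
        pool = list(rng.permutation(expressed))
        membership = {"abc": (0, 1, 2), "ab": (0, 1), "ac": (0, 2), "bc": (1, 2),
                      "a": (0,), "b": (1,), "c": (2,)}
        for direction in ("up", "down"):
            for cell in cells:
                for _ in range(cfg.de_venn.get(cell, 0)):
                    gene = pool.pop()
                    for gi in membership[cell]:
                        planted[gt[gi]][direction].add(gene)
        truth_venn = {d: dict(cfg.de_venn) for d in ("up", "down")}

    tables: Dict[str, List[DERecord]] = {}
    base_means = np.where(
        [i in fail_idx for i in range(n)],
        rng.uniform(0.0, 10.0, size=n),
        rng.uniform(10.5, 2000.0, size=n),
    )
    for g in gt:
        rows = []
        for i, gene in enumerate(genes):
            if gene in planted[g]["up"]:
                padj = float(rng.uniform(0.0, cfg.de_alpha * 0.8))
                lfc = float(rng.uniform(0.5, 4.0))
            elif gene in planted[g]["down"]:
                padj = float(rng.uniform(0.0, cfg.de_alpha * 0.8))
                lfc = float(-rng.uniform(0.5, 4.0))
            else:
                padj = float(rng.uniform(cfg.de_alpha, 1.0))
                lfc = float(rng.normal(0.0, 0.2))
            rows.append(DERecord(gene, float(base_means[i]), lfc, padj))
        tables[g] = rows

    truth = {
        "universe": sorted(expressed),
        "planted": {
            g: {d: sorted(s) for d, s in dirs.items()} for g, dirs in planted.items()
        },
        "venn": truth_venn,
        "null": cfg.de_null,
    }
    return tables, truth
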