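"""Readers and writers for every external text format the pipeline touches.

All I/O is UTF-8, tab-delimited, newline-terminated. Readers validate hard
(malformed numerics carry line numbers); every reader/writer pair round-trips
its in-memory representation exactly for valid files.

Formats: BED3/BED6, narrowPeak (ENCODE 10-column), chrom.sizes, bedGraph
(4-column), aligned-read BED (mapq in column 5), spectral-count TSV,
differential-expression TSV, gene-annotation TSV, flat YAML config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from chipquant.core_intervals import ChromSizes, GenomicInterval, Peak
from chipquant.coverage import CoverageTrack

__all__ = [
    "AlignedRead",
    "SpectralCountRecord",
    "DERecord",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_aligned_reads",
    "write_aligned_reads",
    "read_sc_table",
    "write_sc_table",
    "read_de_table",
    "write_de_table",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_config",
    "write_config",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class AlignedRead:
    """An aligned read: genome-of-origin label, interval, mapping quality."""

    genome: str
    interval: GenomicInterval
    mapq: int

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError(f"mapq must be >= 0, got {self.mapq}")


@dataclass(frozen=True)
class SpectralCountRecord:
    """Per-protein IP vs matched-control spectral counts across replicates."""

    protein_id: str
    sc_ip: Tuple[int, ...]
    sc_control: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sc_ip) != len(self.sc_control) or not self.sc_ip:
            raise ValueError("sc_ip and sc_control must be equal-length, non-empty")
        if any(c < 0 for c in self.sc_ip) or any(c < 0 for c in self.sc_control):
            raise ValueError(f"negative spectral count for {self.protein_id!r}")


@dataclass(frozen=True)
class DERecord:
    """Per-gene expression summary: baseMean, log2 fold change, adjusted p."""

    gene_id: str
    base_mean: float
    log2fc: float
    padj: Optional[float]  # None = missing (DESeq2 independent filtering)

    def __post_init__(self) -> None:
        if self.base_mean < 0:
            raise ValueError(f"baseMean must be >= 0 for {self.gene_id!r}")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj out of [0,1] for {self.gene_id!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's strand-resolved 5' start position."""

    gene_id: str
    chrom: str
    start: int  # 0-based, already the 5' end for the given strand
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene start must be >= 0 for {self.gene_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-' for {self.gene_id!r}")


# ---------------------------------------------------------------------------
# helpers


def _parse_int(token: str, path: PathLike, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: unparseable {what} {token!r}") from exc


def _parse_float(token: str, path: PathLike, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: unparseable {what} {token!r}") from exc


def _data_lines(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# BED / narrowPeak / chrom.sizes


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3+ (extra columns ignored) into intervals."""
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        out.append(
            GenomicInterval(
                cols[0],
                _parse_int(cols[1], path, lineno, "start"),
                _parse_int(cols[2], path, lineno, "end"),
            )
        )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path: PathLike) -> List[Peak]:
    """ENCODE narrowPeak: 10 columns, summit offset in column 10.

    The summit offset is converted to an absolute 0-based position. An offset
    of -1 (summit not called) is a hard error; this pipeline requires summits.
    """
    peaks = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 10:
            raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns")
        iv = GenomicInterval(
            cols[0],
            _parse_int(cols[1], path, lineno, "start"),
            _parse_int(cols[2], path, lineno, "end"),
        )
        offset = _parse_int(cols[9], path, lineno, "summit offset")
        if offset < 0:
            raise ValueError(f"{path}:{lineno}: missing summit (offset {offset})")
        peaks.append(
            Peak(
                interval=iv,
                summit=iv.start + offset,
                score=_parse_float(cols[6], path, lineno, "signalValue"),
            )
        )
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t0\t.\t"
                f"{p.score:g}\t-1\t-1\t{p.summit - iv.start}\n"
            )


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    sizes: Dict[str, int] = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: chrom.sizes needs 2 columns")
        if cols[0] in sizes:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {cols[0]!r}")
        sizes[cols[0]] = _parse_int(cols[1], path, lineno, "length")
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# bedGraph <-> CoverageTrack


def read_bedgraph(path: PathLike, sizes: ChromSizes, bin: int = 10) -> CoverageTrack:
    """Resample a bedGraph onto fixed bins by length-weighted mean.

    Uncovered bases contribute 0. Records beyond the chromosome length or
    overlapping each other are hard errors.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    track = CoverageTrack.zeros(sizes, bin)
    # accumulate value*bases per bin, then divide by bin-width in bases
    covered_end: Dict[str, int] = {}
    records: List[Tuple[str, int, int, float]] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom = cols[0]
        start = _parse_int(cols[1], path, lineno, "start")
        end = _parse_int(cols[2], path, lineno, "end")
        value = _parse_float(cols[3], path, lineno, "value")
        if chrom not in sizes:
            raise KeyError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > sizes[chrom]:
            raise ValueError(
                f"{path}:{lineno}: record [{start},{end}) beyond {chrom} length "
                f"{sizes[chrom]}"
            )
        records.append((chrom, start, end, value))
    records.sort(key=lambda r: (r[0], r[1]))
    for chrom, start, end, value in records:
        if start < covered_end.get(chrom, 0):
            raise ValueError(f"{path}: overlapping bedGraph records on {chrom}")
        covered_end[chrom] = end
        arr = track.data[chrom]
        first, last = start // bin, (end - 1) // bin
        for k in range(first, last + 1):
            lo, hi = max(start, k * bin), min(end, (k + 1) * bin)
            arr[k] += value * (hi - lo)
    for chrom, arr in track.data.items():
        # full bins have width `bin`; the trailing partial bin is averaged over
        # its true base count so mean-resampling stays exact at chromosome ends
        widths = np.full(len(arr), float(bin))
        rem = sizes[chrom] - (len(arr) - 1) * bin
        widths[-1] = rem
        arr /= widths
    return track


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Emit one record per run of equal-valued bins; zero runs are skipped."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            chrom_len = track.sizes[chrom]
            run_start = 0
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != arr[run_start]:
                    value = arr[run_start]
                    if value != 0.0:
                        s = run_start * track.bin
                        e = min(i * track.bin, chrom_len)
                        fh.write(f"{chrom}\t{s}\t{e}\t{value:.10g}\n")
                    run_start = i


# ---------------------------------------------------------------------------
# aligned reads (BED6-like: chrom start end name mapq strand)


def read_aligned_reads(
    path: PathLike, genome_map: Mapping[str, str]
) -> List[AlignedRead]:
    """Read aligned reads; genome label resolved by chromosome-name prefix.

    ``genome_map`` maps chromosome-name prefixes to genome labels (e.g.
    ``{"ce_": "target", "cb_": "spike"}``). A chromosome matching no prefix is
    a hard error.
    """
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 5:
            raise ValueError(f"{path}:{lineno}: read BED needs >= 5 columns")
        iv = GenomicInterval(
            cols[0],
            _parse_int(cols[1], path, lineno, "start"),
            _parse_int(cols[2], path, lineno, "end"),
        )
        out.append(
            AlignedRead(
                genome=resolve_genome(iv.chrom, genome_map),
                interval=iv,
                mapq=_parse_int(cols[4], path, lineno, "mapq"),
            )
        )
    return out


def resolve_genome(chrom: str, genome_map: Mapping[str, str]) -> str:
    for prefix, label in genome_map.items():
        if chrom.startswith(prefix):
            return label
    raise KeyError(f"chromosome {chrom!r} matches no genome prefix in {list(genome_map)}")


def write_aligned_reads(reads: Sequence[AlignedRead], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tread_{i}\t{r.mapq}\t.\n")


# ---------------------------------------------------------------------------
# spectral-count tables


def read_sc_table(path: PathLike) -> List[SpectralCountRecord]:
    """TSV with header ``protein_id  ip_1..ip_k  control_1..control_k``.

    Blank cells are read as 0; duplicate protein ids and negative counts are
    hard errors.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ip_cols = [i for i, h in enumerate(header) if h.startswith("ip_")]
        ctl_cols = [i for i, h in enumerate(header) if h.startswith("control_")]
        if not ip_cols or len(ip_cols) != len(ctl_cols):
            raise ValueError(
                f"{path}: header must name equal numbers of ip_* and control_* columns"
            )
        out: List[SpectralCountRecord] = []
        seen = set()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            pid = cols[0]
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
            seen.add(pid)

            def cell(i: int) -> int:
                tok = cols[i] if i < len(cols) else ""
                if tok == "":
                    return 0
                v = _parse_int(tok, path, lineno, "spectral count")
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative spectral count {v}")
                return v

            out.append(
                SpectralCountRecord(
                    protein_id=pid,
                    sc_ip=tuple(cell(i) for i in ip_cols),
                    sc_control=tuple(cell(i) for i in ctl_cols),
                )
            )
        return out


def write_sc_table(records: Sequence[SpectralCountRecord], path: PathLike) -> None:
    if not records:
        n_rep = 1
    else:
        n_rep = len(records[0].sc_ip)
    header = (
        ["protein_id"]
        + [f"ip_{i+1}" for i in range(n_rep)]
        + [f"control_{i+1}" for i in range(n_rep)]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            cells = [rec.protein_id] + [str(c) for c in rec.sc_ip + rec.sc_control]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# differential-expression tables


_DE_HEADER = ["gene", "baseMean", "log2FoldChange", "padj"]


def read_de_table(path: PathLike) -> List[DERecord]:
    """TSV with header gene/baseMean/log2FoldChange/padj; "NA" padj = missing."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = {name: header.index(name) for name in _DE_HEADER}
        except ValueError as exc:
            raise ValueError(f"{path}: header must contain {_DE_HEADER}") from exc
        out: List[DERecord] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            padj_tok = cols[idx["padj"]]
            padj = (
                None
                if padj_tok in ("NA", "")
                else _parse_float(padj_tok, path, lineno, "padj")
            )
            out.append(
                DERecord(
                    gene_id=cols[idx["gene"]],
                    base_mean=_parse_float(cols[idx["baseMean"]], path, lineno, "baseMean"),
                    log2fc=_parse_float(
                        cols[idx["log2FoldChange"]], path, lineno, "log2FoldChange"
                    ),
                    padj=padj,
                )
            )
        return out


def write_de_table(records: Sequence[DERecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DE_HEADER) + "\n")
        for rec in records:
            padj = "NA" if rec.padj is None else repr(rec.padj)
            fh.write(
                f"{rec.gene_id}\t{rec.base_mean!r}\t{rec.log2fc!r}\t{padj}\n"
            )


# ---------------------------------------------------------------------------
# gene annotations (minimal gene-start table, not a GFF parser)


def read_gene_annotations(path: PathLike) -> List[GeneAnnotation]:
    """TSV: gene_id, chrom, start (0-based 5' end), strand."""
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise ValueError(f"{path}:{lineno}: gene table needs 4 columns")
        out.append(
            GeneAnnotation(
                gene_id=cols[0],
                chrom=cols[1],
                start=_parse_int(cols[2], path, lineno, "start"),
                strand=cols[3],
            )
        )
    return out


def write_gene_annotations(genes: Sequence[GeneAnnotation], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# flat config


def read_config(path: PathLike) -> Dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def write_config(cfg: Mapping, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
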