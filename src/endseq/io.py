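"""Genomic containers and text-format I/O.

Coordinates are 0-based half-open (BED convention) everywhere. A sequenced
DNA end is a single base position; coverage tracks count read ends per bin,
and RPKM/RPM normalization uses the read-end count of the whole library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, ParseError, UndefinedSignalError

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class BreakSite:
    """A break interval plus the summit at which all statistics anchor."""

    site_id: str
    interval: GenomicInterval
    summit: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @classmethod
    def from_summit(cls, site_id: str, chrom: str, summit: int, flank: int = 1000) -> "BreakSite":
        """Build a summit-centered site spanning ``summit +/- flank``."""
        start = max(0, summit - flank)
        return cls(site_id, GenomicInterval(chrom, start, summit + flank + 1), summit)


class ReadEndSet:
    """Positions and strands of sequenced DNA ends for one sample.

    Backed by a DataFrame with columns ``chrom`` (str), ``pos`` (int, 0-based)
    and ``strand`` (one of ``+ - .``).
    """

    COLUMNS = ("chrom", "pos", "strand")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"ReadEndSet frame missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        positions: Sequence[int],
        strands: Sequence[str],
    ) -> "ReadEndSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": np.asarray(chroms, dtype=object),
                    "pos": np.asarray(positions, dtype=np.int64),
                    "strand": np.asarray(strands, dtype=object),
                }
            )
        )

    @classmethod
    def empty(cls) -> "ReadEndSet":
        return cls.from_arrays([], [], [])

    @property
    def total_reads(self) -> int:
        return len(self.df)

    def subset_strand(self, strand: str) -> "ReadEndSet":
        if strand not in _STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        return ReadEndSet(self.df[self.df["strand"] == strand].reset_index(drop=True))

    def sorted(self) -> "ReadEndSet":
        return ReadEndSet(
            self.df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
                drop=True
            )
        )

    def to_bed(self, path: str | Path) -> None:
        """Write 6-column BED, one 1-bp record per read end, coordinate-sorted."""
        df = self.sorted().df
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "name": [f"read_{i:07d}" for i in range(len(df))],
                "score": 0,
                "strand": df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ReadEndSet":
        rows = _parse_bed_lines(path)
        if not rows:
            return cls.empty()
        chroms, positions, strands = [], [], []
        for fields, lineno in rows:
            chroms.append(fields[0])
            positions.append(_parse_coord(fields[1], path, lineno))
            strands.append(fields[5] if len(fields) >= 6 else ".")
        return cls.from_arrays(chroms, positions, strands)


def _parse_coord(text: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise ParseError(f"{path} line {lineno}: non-integer coordinate {text!r}") from exc


def _parse_bed_lines(path: str | Path) -> list[tuple[list[str], int]]:
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected >= 3 tab-separated fields")
            rows.append((fields, lineno))
    return rows


def read_bed(path: str | Path) -> list:
    """Read a BED file into intervals, or break sites when a summit column is present.

    Layout: ``chrom start end [name score strand [summit]]``; a 7th column is
    interpreted as the absolute summit coordinate and yields :class:`BreakSite`.
    """
    rows = _parse_bed_lines(path)
    out: list = []
    for fields, lineno in rows:
        chrom = fields[0]
        start = _parse_coord(fields[1], path, lineno)
        end = _parse_coord(fields[2], path, lineno)
        strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
        try:
            interval = GenomicInterval(chrom, start, end, strand)
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from exc
        if len(fields) >= 7:
            summit = _parse_coord(fields[6], path, lineno)
            name = fields[3] if len(fields) >= 4 else f"site_{lineno}"
            try:
                out.append(BreakSite(name, interval, summit))
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
        else:
            out.append(interval)
    return out


def write_bed(items: Iterable, path: str | Path) -> None:
    """Write intervals or break sites back to BED (sites carry a summit column)."""
    with open(path, "w") as handle:
        for item in items:
            if isinstance(item, BreakSite):
                iv = item.interval
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.site_id}\t0\t"
                    f"{iv.strand}\t{item.summit}\n"
                )
            else:
                handle.write(f"{item.chrom}\t{item.start}\t{item.end}\n")


class CoverageTrack:
    """Per-chromosome binned read-end counts plus the library size.

    ``counts[chrom][j]`` is the number of read ends with
    ``j * bin_width <= pos < (j + 1) * bin_width``. ``total_reads`` is the
    library size used for RPM/RPKM scaling; for strand-split tracks it should
    remain the full library's read count so normalized values stay comparable.
    """

    def __init__(self, bin_width: int, counts: Mapping[str, np.ndarray], total_reads: int):
        if bin_width < 1:
            raise ConfigurationError("bin_width must be >= 1")
        self.bin_width = int(bin_width)
        self.counts = {c: np.asarray(a, dtype=np.float64) for c, a in counts.items()}
        self.total_reads = int(total_reads)

    def count_in(self, chrom: str, start: int, end: int) -> float:
        """Read ends in [start, end); partial bins contribute fractionally.

        Exact whenever the interval aligns to bin edges (always at bin_width 1).
        """
        if chrom not in self.counts or end <= start:
            return 0.0
        arr = self.counts[chrom]
        bw = self.bin_width
        start = max(start, 0)
        end = min(end, len(arr) * bw)
        if end <= start:
            return 0.0
        b0, b1 = start // bw, (end - 1) // bw
        if b0 == b1:
            return float(arr[b0] * (end - start) / bw)
        total = arr[b0] * ((b0 + 1) * bw - start) / bw + arr[b1] * (end - b1 * bw) / bw
        if b1 > b0 + 1:
            total += arr[b0 + 1 : b1].sum()
        return float(total)

    def total_count(self) -> float:
        return float(sum(a.sum() for a in self.counts.values()))


def coverage_from_reads(
    reads: ReadEndSet,
    bin_width: int,
    chrom_sizes: Mapping[str, int],
    strand: str | None = None,
    total_reads: int | None = None,
) -> CoverageTrack:
    """Bin read ends into a :class:`CoverageTrack`.

    ``strand`` restricts to one strand while ``total_reads`` (default: the
    number of binned reads) can pin the normalization denominator to the full
    library size.
    """
    if bin_width < 1:
        raise ConfigurationError("bin_width must be >= 1")
    df = reads.df if strand is None else reads.subset_strand(strand).df
    counts: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        nbins = math.ceil(size / bin_width)
        sub = df[df["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if pos.size:
            bad = (pos < 0) | (pos >= size)
            if bad.any():
                p = int(pos[bad.argmax()])
                raise ValueError(f"read at {chrom}:{p} beyond chromosome end ({size})")
        counts[chrom] = np.bincount(pos // bin_width, minlength=nbins).astype(np.float64)
    unknown = set(df["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"reads on chromosomes missing from chrom_sizes: {sorted(unknown)}")
    n = len(df) if total_reads is None else int(total_reads)
    return CoverageTrack(bin_width, counts, n)


def rpkm(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Reads per kilobase per million library reads inside ``interval``."""
    if track.total_reads <= 0:
        raise UndefinedSignalError("RPKM undefined for an empty library")
    reads = track.count_in(interval.chrom, interval.start, interval.end)
    return reads / (interval.length / 1000.0) / (track.total_reads / 1e6)


def write_bedgraph(
    track: CoverageTrack,
    path: str | Path,
    scale: str = "raw",
    spike_factor: float | None = None,
) -> None:
    """Write a bedGraph; zero bins are omitted, equal adjacent bins merged.

    ``scale``: ``raw`` (counts), ``rpm`` (counts x 1e6 / library size), or
    ``rpm_spike`` (RPM further divided by ``spike_factor``). Values carry six
    significant digits; merging compares the formatted values.
    """
    scale = scale.lower()
    if scale not in {"raw", "rpm", "rpm_spike"}:
        raise ConfigurationError(f"unknown bedGraph scale {scale!r}")
    if scale == "rpm_spike" and (spike_factor is None or spike_factor <= 0):
        raise ConfigurationError("rpm_spike scale requires a positive spike_factor")
    if scale in {"rpm", "rpm_spike"} and track.total_reads <= 0:
        raise UndefinedSignalError("RPM scaling undefined for an empty library")
    with open(path, "w") as handle:
        for chrom in sorted(track.counts):
            values = track.counts[chrom]
            if scale != "raw":
                values = values * 1e6 / track.total_reads
                if scale == "rpm_spike":
                    values = values / spike_factor
            bw = track.bin_width
            run_start = None
            run_text = None
            for j, v in enumerate(values):
                text = format(v, ".6g") if v != 0 else None
                if text != run_text:
                    if run_text is not None:
                        handle.write(f"{chrom}\t{run_start * bw}\t{j * bw}\t{run_text}\n")
                    run_start, run_text = j, text
            if run_text is not None:
                handle.write(f"{chrom}\t{run_start * bw}\t{len(values) * bw}\t{run_text}\n")


def read_bedgraph(
    path: str | Path,
    bin_width: int,
    chrom_sizes: Mapping[str, int],
    total_reads: int | None = None,
) -> CoverageTrack:
    """Read a bedGraph written on the same bin grid back into a track."""
    counts = {
        chrom: np.zeros(math.ceil(size / bin_width), dtype=np.float64)
        for chrom, size in chrom_sizes.items()
    }
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path} line {lineno}: expected 4 fields")
            chrom, start, end, value = fields
            start_i, end_i = _parse_coord(start, path, lineno), _parse_coord(end, path, lineno)
            if chrom not in counts:
                raise ParseError(f"{path} line {lineno}: unknown chromosome {chrom!r}")
            if start_i % bin_width or (end_i % bin_width and end_i != chrom_sizes[chrom]):
                raise ParseError(f"{path} line {lineno}: span not aligned to {bin_width} bp bins")
            counts[chrom][start_i // bin_width : math.ceil(end_i / bin_width)] = float(value)
    total = int(sum(a.sum() for a in counts.values())) if total_reads is None else total_reads
    return CoverageTrack(bin_width, counts, total)


def subtract_blacklist(
    sites: Sequence[BreakSite], blacklist: Sequence[GenomicInterval]
) -> list[BreakSite]:
    """Drop every site whose interval overlaps a blacklist interval by >= 1 bp."""
    if not blacklist:
        return list(sites)
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept = []
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None or not tree.overlap(site.interval.start, site.interval.end):
            kept.append(site)
    return kept
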