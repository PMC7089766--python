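"""Synthetic END-seq read-end generator with ground-truth lesion tables.

The generator emulates the observable structure of END-seq libraries from
etoposide-treated G1 cells: per cell and break site a TOP2-mediated lesion is
drawn, assigned to one of three species (reversible TOP2cc, irreversible
TOP2cc, protein-free DSB), and emits one sequenced DNA end iff the species is
detectable under the sample's exonuclease cocktail and washout timepoint:

* ExoVII+ExoT blunts protein-linked and protein-free ends, so it sees all
  three species before washout; after washout, reversible complexes have
  re-ligated and vanish.
* ExoT alone cannot process protein-linked ends and sees only protein-free
  DSBs, at any timepoint.

Protein-free lesions observed at a washout timepoint have been exposed to
resection nucleases: their read end is displaced from the summit by an
exponential one-sided resection length truncated at a hard cap, on a uniformly
random side (left ends tagged '-', right ends '+'). All other emissions fall
within a small blunting jitter of the summit. Zinc-finger-nuclease spike-in
sites emit from the spiked-in cell fraction at full penetrance and are never
resected. Uniform background read ends model noise. All randomness flows from
one integer seed; a sample's stream is derived from (seed, sample_id) so each
sample is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SizingError
from .io import ReadEndSet

MIN_SITE_SPACING = 10_000
MIN_EDGE_DISTANCE = 5_000

_FRACTION_TOL = 1e-9


class Nuclease(str, Enum):
    EXOVII_EXOT = "EXOVII_EXOT"
    EXOT_ONLY = "EXOT_ONLY"


class Timepoint(str, Enum):
    PRE_WASHOUT = "PRE_WASHOUT"
    WASHOUT_0H = "WASHOUT_0H"
    WASHOUT_2H = "WASHOUT_2H"


def _coerce_enum(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value))
    except ValueError as exc:
        raise ConfigurationError(
            f"unknown {enum_cls.__name__} value {value!r}; "
            f"expected one of {[e.value for e in enum_cls]}"
        ) from exc


@dataclass
class LesionTruth:
    """Latent per-site lesion parameters (the ground truth the analysis estimates)."""

    site_id: str
    chrom: str
    summit: int
    p_cleaved: float
    f_reversible: float
    f_irreversible: float
    f_free: float
    resection_mean_bp: float
    resection_max_bp: float = 2500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cleaved <= 1.0:
            raise ValueError(f"{self.site_id}: p_cleaved must be in [0, 1]")
        for name in ("f_reversible", "f_irreversible", "f_free"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{self.site_id}: {name} must be in [0, 1]")
        total = self.f_reversible + self.f_irreversible + self.f_free
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"{self.site_id}: species fractions sum to {total}, not 1")
        if self.resection_mean_bp < 0 or self.resection_mean_bp > self.resection_max_bp:
            raise ValueError(
                f"{self.site_id}: need 0 <= resection_mean_bp <= resection_max_bp"
            )


@dataclass
class SimConfig:
    """Genome layout, library composition and default lesion parameters.

    Defaults mirror the study conditions the pipeline is designed for: ZFN
    spike-in cells at a 1:40 (2.5%) library ratio, and an etoposide lesion
    pool decomposing into 76% reversible TOP2cc, 4% irreversible TOP2cc and
    20% protein-free DSBs at drug washout.
    """

    chrom_sizes: Mapping[str, int]
    n_sites: int
    n_spike_sites: int = 0
    spike_in_fraction: float = 0.025
    cells_per_sample: int = 2000
    background_rate: float = 0.05  # expected noise read ends per kb
    summit_jitter_bp: int = 3
    seed: int = 0
    p_cleaved: float = 0.2
    f_reversible: float = 0.76
    f_irreversible: float = 0.04
    f_free: float = 0.20
    resection_mean_bp: float = 400.0
    resection_max_bp: float = 2500.0
    washout_2h_survival: float = 0.5  # extra survival of free+irreversible at 2 h

    def __post_init__(self) -> None:
        if self.n_sites < 0 or self.n_spike_sites < 0:
            raise ConfigurationError("site counts must be non-negative")
        if not 0.0 <= self.spike_in_fraction < 1.0:
            raise ConfigurationError("spike_in_fraction must be in [0, 1)")
        if self.cells_per_sample <= 0:
            raise ConfigurationError("cells_per_sample must be positive")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be non-negative")
        if self.summit_jitter_bp < 0:
            raise ConfigurationError("summit_jitter_bp must be non-negative")
        if not 0.0 <= self.washout_2h_survival <= 1.0:
            raise ConfigurationError("washout_2h_survival must be in [0, 1]")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigurationError(f"chromosome {chrom} has non-positive length")


@dataclass
class SampleMeta:
    """One library: treatment arm, exonuclease cocktail, washout timepoint."""

    sample_id: str
    treatment: str
    nuclease: Nuclease
    timepoint: Timepoint
    spike_in_fraction: float = 0.025
    total_reads: int | None = None

    def __post_init__(self) -> None:
        self.nuclease = _coerce_enum(self.nuclease, Nuclease)
        self.timepoint = _coerce_enum(self.timepoint, Timepoint)
        if not 0.0 <= self.spike_in_fraction < 1.0:
            raise ConfigurationError("spike_in_fraction must be in [0, 1)")
        if self.total_reads is not None and self.total_reads <= 0:
            raise ConfigurationError("total_reads must be positive once populated")


def _capacity(size: int) -> int:
    """How many summits fit on a chromosome at the required spacing."""
    usable = size - 2 * MIN_EDGE_DISTANCE
    if usable < 0:
        return 0
    return usable // MIN_SITE_SPACING + 1


def simulate_genome(config: SimConfig) -> tuple[list[LesionTruth], list[tuple[str, int]]]:
    """Place break and spike-in summits, returning truths and spike summits.

    Summits sit >= 10 kb apart and >= 5 kb from chromosome ends so that 5 kb
    resection flanks never overlap a neighbouring site. Deterministic for a
    given config (placement uses the config seed).
    """
    total = config.n_sites + config.n_spike_sites
    if total == 0:
        return [], []
    rng = np.random.default_rng([int(config.seed), zlib.crc32(b"genome")])
    chroms = sorted(config.chrom_sizes)
    caps = {c: _capacity(config.chrom_sizes[c]) for c in chroms}
    if sum(caps.values()) < total:
        raise SizingError(
            f"genome holds at most {sum(caps.values())} summits at "
            f"{MIN_SITE_SPACING} bp spacing; {total} requested"
        )
    # proportional allocation by capacity, largest remainder, clipped to capacity
    alloc = {c: 0 for c in chroms}
    remaining = total
    quota = {c: total * caps[c] / sum(caps.values()) for c in chroms}
    for c in chroms:
        alloc[c] = min(int(quota[c]), caps[c])
        remaining -= alloc[c]
    order = sorted(chroms, key=lambda c: (quota[c] - int(quota[c])), reverse=True)
    i = 0
    while remaining > 0:
        c = order[i % len(order)]
        if alloc[c] < caps[c]:
            alloc[c] += 1
            remaining -= 1
        i += 1

    placements: list[tuple[str, int]] = []
    for c in chroms:
        k = alloc[c]
        if k == 0:
            continue
        size = config.chrom_sizes[c]
        slack = size - 2 * MIN_EDGE_DISTANCE - (k - 1) * MIN_SITE_SPACING
        offsets = np.sort(rng.uniform(0.0, slack, size=k)).astype(np.int64)
        for i_site, off in enumerate(offsets):
            placements.append((c, int(MIN_EDGE_DISTANCE + off + i_site * MIN_SITE_SPACING)))

    idx = rng.permutation(len(placements))
    spike_idx = set(idx[: config.n_spike_sites].tolist())
    truths: list[LesionTruth] = []
    spike_sites: list[tuple[str, int]] = []
    n_site = n_spike = 0
    for j, (chrom, summit) in enumerate(placements):
        if j in spike_idx:
            n_spike += 1
            spike_sites.append((chrom, summit))
        else:
            n_site += 1
            truths.append(
                LesionTruth(
                    site_id=f"site_{n_site:04d}",
                    chrom=chrom,
                    summit=summit,
                    p_cleaved=config.p_cleaved,
                    f_reversible=config.f_reversible,
                    f_irreversible=config.f_irreversible,
                    f_free=config.f_free,
                    resection_mean_bp=config.resection_mean_bp,
                    resection_max_bp=config.resection_max_bp,
                )
            )
    return truths, spike_sites


def _truncated_exponential(rng, mean: float, cap: float, n: int) -> np.ndarray:
    """Integer resection lengths from Exp(mean) truncated (renormalized) at cap."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    u = rng.random(n)
    z = -np.expm1(-cap / mean)  # P(X < cap) under the untruncated law
    return np.floor(-mean * np.log1p(-u * z)).astype(np.int64)


def _observable_counts(rng, truth: LesionTruth, meta: SampleMeta, config: SimConfig):
    """Split one site's lesion pool into (unresected, resected) emissions."""
    n_cleaved = rng.binomial(config.cells_per_sample, truth.p_cleaved)
    n_rev, n_irr, n_free = rng.multinomial(
        n_cleaved, [truth.f_reversible, truth.f_irreversible, truth.f_free]
    )
    if meta.timepoint == Timepoint.WASHOUT_2H:
        n_irr = rng.binomial(n_irr, config.washout_2h_survival)
        n_free = rng.binomial(n_free, config.washout_2h_survival)
    if meta.nuclease == Nuclease.EXOVII_EXOT:
        protein_linked = n_irr + (n_rev if meta.timepoint == Timepoint.PRE_WASHOUT else 0)
    else:
        protein_linked = 0
    if meta.timepoint == Timepoint.PRE_WASHOUT:
        return protein_linked + n_free, 0
    return protein_linked, n_free


def simulate_sample(
    truths: Sequence[LesionTruth],
    spike_sites: Sequence[tuple[str, int]],
    meta: SampleMeta,
    config: SimConfig,
) -> ReadEndSet:
    """Emit one library of read ends for a sample; fills ``meta.total_reads``.

    An untreated control library is obtained by passing an empty truth list
    (spike-in and background still emit).
    """
    rng = np.random.default_rng(
        [int(config.seed), zlib.crc32(meta.sample_id.encode()), zlib.crc32(b"sample")]
    )
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    j = config.summit_jitter_bp

    def emit(chrom: str, pos: np.ndarray, strand: np.ndarray) -> None:
        if pos.size:
            chroms.append(np.full(pos.size, chrom, dtype=object))
            positions.append(pos.astype(np.int64))
            strands.append(strand)

    for truth in truths:
        n_summit, n_resected = _observable_counts(rng, truth, meta, config)
        if n_summit:
            pos = truth.summit + rng.integers(-j, j + 1, size=n_summit)
            emit(truth.chrom, pos, rng.choice(np.array(["+", "-"], dtype=object), n_summit))
        if n_resected:
            dist = _truncated_exponential(
                rng, truth.resection_mean_bp, truth.resection_max_bp, n_resected
            )
            left = rng.random(n_resected) < 0.5
            pos = np.where(left, truth.summit - dist, truth.summit + dist)
            strand = np.where(left, "-", "+").astype(object)
            emit(truth.chrom, pos, strand)

    for chrom, summit in spike_sites:
        n = rng.binomial(config.cells_per_sample, meta.spike_in_fraction)
        if n:
            pos = summit + rng.integers(-j, j + 1, size=n)
            emit(chrom, pos, rng.choice(np.array(["+", "-"], dtype=object), n))

    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        n_bg = rng.poisson(config.background_rate * size / 1000.0)
        if n_bg:
            pos = rng.integers(0, size, size=n_bg)
            emit(chrom, pos, rng.choice(np.array(["+", "-"], dtype=object), n_bg))

    if not positions:
        reads = ReadEndSet.empty()
    else:
        reads = ReadEndSet.from_arrays(
            np.concatenate(chroms), np.concatenate(positions), np.concatenate(strands)
        ).sorted()
    meta.total_reads = reads.total_reads if reads.total_reads > 0 else None
    return reads


TRUTH_COLUMNS = [
    "site_id",
    "chrom",
    "summit",
    "p_cleaved",
    "f_reversible",
    "f_irreversible",
    "f_free",
    "resection_mean_bp",
    "resection_max_bp",
]


def write_truth(
    truths: Sequence[LesionTruth],
    spike_sites: Sequence[tuple[str, int]],
    path: str | Path,
    spike_path: str | Path | None = None,
) -> None:
    """Write the lesion truth table (TSV); spike summits go to ``spike_path``."""
    frame = pd.DataFrame(
        [
            {col: getattr(t, col) for col in TRUTH_COLUMNS}
            for t in truths
        ],
        columns=TRUTH_COLUMNS,
    )
    for col in ("p_cleaved", "f_reversible", "f_irreversible", "f_free"):
        if len(frame):
            frame[col] = frame[col].map(lambda v: format(v, ".6f"))
    frame.to_csv(path, sep="\t", index=False)
    if spike_path is not None:
        with open(spike_path, "w") as handle:
            handle.write("chrom\tsummit\n")
            for chrom, summit in spike_sites:
                handle.write(f"{chrom}\t{summit}\n")


def read_truth(path: str | Path) -> list[LesionTruth]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: truth table missing columns {sorted(missing)}")
    truths = []
    for row in frame.itertuples(index=False):
        f_rev, f_irr, f_free = row.f_reversible, row.f_irreversible, row.f_free
        total = f_rev + f_irr + f_free
        if abs(total - 1.0) > 1e-4:
            raise ParseError(f"{path}: fractions for {row.site_id} sum to {total}")
        truths.append(
            LesionTruth(
                site_id=str(row.site_id),
                chrom=str(row.chrom),
                summit=int(row.summit),
                p_cleaved=float(row.p_cleaved),
                f_reversible=f_rev / total,
                f_irreversible=f_irr / total,
                f_free=f_free / total,
                resection_mean_bp=float(row.resection_mean_bp),
                resection_max_bp=float(row.resection_max_bp),
            )
        )
    return truths


def read_spike_sites(path: str | Path) -> list[tuple[str, int]]:
    frame = pd.read_csv(path, sep="\t")
    return [(str(r.chrom), int(r.summit)) for r in frame.itertuples(index=False)]


SHEET_COLUMNS = [
    "sample_id",
    "treatment",
    "nuclease",
    "timepoint",
    "spike_in_fraction",
    "reads_path",
]


def write_sample_sheet(
    metas: Sequence[SampleMeta], reads_paths: Mapping[str, str], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "treatment": m.treatment,
                "nuclease": m.nuclease.value,
                "timepoint": m.timepoint.value,
                "spike_in_fraction": m.spike_in_fraction,
                "reads_path": reads_paths[m.sample_id],
            }
            for m in metas
        ],
        columns=SHEET_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[tuple[SampleMeta, str]]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(SHEET_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            treatment=str(row.treatment),
            nuclease=row.nuclease,
            timepoint=row.timepoint,
            spike_in_fraction=float(row.spike_in_fraction),
        )
        out.append((meta, str(row.reads_path)))
    return out
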