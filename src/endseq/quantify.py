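"""Break-site detection, per-site signal, and spike-in cell-percentage scaling.

A break site counts as detected when its treated RPKM exceeds a fold threshold
over the untreated control (default > 10-fold, with a small pseudocount added
to the control so zero-background sites are well-defined). Spike-in scaling
converts each peak's RPKM to the percentage of cells carrying the lesion:
with zinc-finger-nuclease spike-in cells mixed in at fraction ``f`` of the
library, the spike summits report what ``100 x f`` cell-percent of signal
looks like, so ``cell% = peak_rpkm / mean_spike_rpkm x 100 x f`` (the
familiar factor 2.5 at a 1:40 ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, NormalizationError, UndefinedSignalError
from .io import BreakSite, CoverageTrack, GenomicInterval, rpkm

logger = logging.getLogger(__name__)


@dataclass
class PeakSignal:
    site_id: str
    rpkm: float
    cell_percentage: float | None
    detected: bool

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError("rpkm must be >= 0")
        if self.cell_percentage is not None and self.cell_percentage < 0:
            raise ValueError("cell_percentage must be >= 0")


@dataclass
class SpikeInStats:
    """Per-spike-site RPKM and the mean used as the normalization denominator."""

    per_site_rpkm: list[float]
    mean_rpkm: float
    spike_in_fraction: float

    def __post_init__(self) -> None:
        if not self.per_site_rpkm:
            raise NormalizationError("no spike-in sites")
        if self.mean_rpkm < 0:
            raise ValueError("mean_rpkm must be >= 0")


def cell_percentage_factor(spike_in_fraction: float) -> float:
    """Multiplier turning spike-normalized RPKM into cell-percent (2.5 at 1:40)."""
    if not 0.0 < spike_in_fraction < 1.0:
        raise NormalizationError("spike_in_fraction must be in (0, 1)")
    return 100.0 * spike_in_fraction


def detect_sites(
    track: CoverageTrack,
    control: CoverageTrack,
    sites: Sequence[BreakSite],
    fold_threshold: float = 10.0,
    pseudocount_rpkm: float = 0.1,
) -> pd.DataFrame:
    """Fold-enrichment detection of candidate sites over an untreated control.

    Returns a frame with per-site treated/control RPKM, the fold ratio, and
    the strict ``fold > fold_threshold`` flag.
    """
    if track.bin_width != control.bin_width:
        raise ConfigurationError(
            f"treated ({track.bin_width} bp) and control ({control.bin_width} bp) "
            "tracks must share a bin width"
        )
    rows = []
    for site in sites:
        r_t = rpkm(track, site.interval)
        r_c = rpkm(control, site.interval)
        fold = r_t / (r_c + pseudocount_rpkm) if (r_c + pseudocount_rpkm) > 0 else np.inf
        rows.append(
            {
                "site_id": site.site_id,
                "rpkm": r_t,
                "rpkm_control": r_c,
                "fold": fold,
                "detected": fold > fold_threshold,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "rpkm", "rpkm_control", "fold", "detected"])


def spike_in_factor(
    track: CoverageTrack,
    spike_sites: Sequence[tuple[str, int]],
    window_bp: int = 2000,
    spike_in_fraction: float = 0.025,
) -> SpikeInStats:
    """Mean RPKM in summit-centered windows over the spike-in break sites."""
    if not spike_sites:
        raise NormalizationError("spike-in normalization needs >= 1 spike site")
    if window_bp < 1:
        raise ConfigurationError("window_bp must be >= 1")
    per_site = []
    for chrom, summit in spike_sites:
        half = window_bp // 2
        iv = GenomicInterval(chrom, max(0, summit - half), summit - half + window_bp)
        per_site.append(rpkm(track, iv))
    mean = float(np.mean(per_site))
    if mean <= 0:
        raise NormalizationError("zero spike-in signal at every spike site")
    return SpikeInStats(per_site, mean, spike_in_fraction)


def to_cell_percentage(rpkm_peak: float, spike: SpikeInStats) -> float:
    """Percent of cells bearing the lesion, via spike-in calibration.

    END-seq signal is concentrated at summits, so the per-kilobase term of
    RPKM does not cancel between peak and spike windows of different
    lengths: quantify peaks in windows matched to ``spike.window_bp`` when
    the absolute cell-percentage scale matters. Ratios of cell-percentages
    across samples (persistence, species fractions) are insensitive to a
    common window mismatch.
    """
    if spike.mean_rpkm <= 0:
        raise NormalizationError("spike mean RPKM must be positive")
    return rpkm_peak / spike.mean_rpkm * cell_percentage_factor(spike.spike_in_fraction)


def quantify_sites(
    track: CoverageTrack,
    sites: Sequence[BreakSite],
    spike: SpikeInStats | None = None,
    detected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site RPKM (and cell-percentage when spike stats are supplied)."""
    flags = (
        dict(zip(detected["site_id"], detected["detected"])) if detected is not None else {}
    )
    rows = []
    for site in sites:
        r = rpkm(track, site.interval)
        rows.append(
            {
                "site_id": site.site_id,
                "chrom": site.chrom,
                "summit": site.summit,
                "rpkm": r,
                "cell_percentage": to_cell_percentage(r, spike) if spike else np.nan,
                "detected": bool(flags.get(site.site_id, True)),
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "summit", "rpkm", "cell_percentage", "detected"]
    )


def overlap_sites(
    a: Sequence[BreakSite], b: Sequence[BreakSite], max_summit_distance: int = 250
) -> tuple[int, int, int]:
    """Venn counts (|a only|, |shared|, |b only|) by greedy nearest-summit matching.

    Candidate pairs are summits on the same chromosome within
    ``max_summit_distance``; pairs are matched nearest-first and each site is
    used at most once.
    """
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for jb, site in enumerate(b):
        by_chrom_b.setdefault(site.chrom, []).append((site.summit, jb))
    for lst in by_chrom_b.values():
        lst.sort()
    pairs = []  # (distance, ia, jb)
    for ia, site in enumerate(a):
        cand = by_chrom_b.get(site.chrom, [])
        summits = [s for s, _ in cand]
        lo = np.searchsorted(summits, site.summit - max_summit_distance)
        hi = np.searchsorted(summits, site.summit + max_summit_distance, side="right")
        for s, jb in cand[lo:hi]:
            pairs.append((abs(s - site.summit), ia, jb))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, ia, jb in pairs:
        if ia in used_a or jb in used_b:
            continue
        used_a.add(ia)
        used_b.add(jb)
        shared += 1
    return len(a) - shared, shared, len(b) - shared


def correlate_replicates(signal_a: Sequence[float], signal_b: Sequence[float]) -> float:
    """Pearson correlation of paired per-site signals across two replicates."""
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ConfigurationError("need two paired vectors of equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedSignalError("correlation undefined for a constant signal vector")
    return float(stats.pearsonr(a, b).statistic)
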