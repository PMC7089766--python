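"""Sliding-window DNA end-resection endpoint caller.

Resection of a protein-free break produces END-seq signal spreading away from
the break summit. The caller profiles each side of a summit in fifty 50 bp
bins (summit to 2.5 kb), takes the *maximum* signal over the next fifty bins
(2.5-5 kb) as that side's background, and slides a 10-bin window outward from
the summit: at the first window position where more than half of the bins are
at or below background, the last bin inside the window still above background
marks the maximum resection endpoint. A side where no window ever satisfies
the majority rule is called resected to the full 2.5 kb scan; a side whose
very first window triggers with no above-background bin is called 0. A break
qualifies as resected when the larger of its two endpoints exceeds 100 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SiteNearEdgeError
from .io import BreakSite, CoverageTrack

logger = logging.getLogger(__name__)

BIN_BP = 50
N_SIGNAL_BINS = 50        # summit .. 2.5 kb
N_BACKGROUND_BINS = 50    # 2.5 kb .. 5 kb
SCAN_BP = BIN_BP * N_SIGNAL_BINS
FLANK_BP = BIN_BP * (N_SIGNAL_BINS + N_BACKGROUND_BINS)
WINDOW_BINS = 10
RESECTED_MIN_BP = 100


class StrandMode(str, Enum):
    UNSTRANDED = "UNSTRANDED"
    STRANDED = "STRANDED"


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


@dataclass
class BinProfile:
    """Per-side binned RPKM around a summit: 50 signal + 50 background bins."""

    site_id: str
    side: Side
    signal_bins: np.ndarray
    background_bins: np.ndarray
    bin_width: int = BIN_BP

    def __post_init__(self) -> None:
        self.signal_bins = np.asarray(self.signal_bins, dtype=float)
        self.background_bins = np.asarray(self.background_bins, dtype=float)
        if len(self.signal_bins) != N_SIGNAL_BINS:
            raise ValueError(f"expected {N_SIGNAL_BINS} signal bins")
        if len(self.background_bins) != N_BACKGROUND_BINS:
            raise ValueError(f"expected {N_BACKGROUND_BINS} background bins")
        if (self.signal_bins < 0).any() or (self.background_bins < 0).any():
            raise ValueError("bin values must be >= 0")


@dataclass
class ResectionCall:
    site_id: str
    endpoint_left: int
    endpoint_right: int
    background_left: float
    background_right: float

    @property
    def max_endpoint(self) -> int:
        return max(self.endpoint_left, self.endpoint_right)

    @property
    def resected(self) -> bool:
        return self.max_endpoint > RESECTED_MIN_BP


def _bin_rpkm(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    count = track.count_in(chrom, start, end)
    return count / ((end - start) / 1000.0) / (track.total_reads / 1e6)


def bin_profile(
    track: CoverageTrack,
    site: BreakSite,
    mode: StrandMode | str = StrandMode.UNSTRANDED,
    plus_track: CoverageTrack | None = None,
    minus_track: CoverageTrack | None = None,
) -> tuple[BinProfile, BinProfile]:
    """Profile both sides of a summit; returns (LEFT, RIGHT).

    Bin ``i`` (1-based) on the RIGHT covers ``[summit + (i-1)*50,
    summit + i*50)``; LEFT bins mirror it. In STRANDED mode the LEFT profile
    is built from minus-strand coverage and the RIGHT from plus-strand
    (resected DNA ends point back toward the summit), so both strand tracks
    must be supplied, normalized to the full library size.
    """
    mode = StrandMode(mode) if not isinstance(mode, StrandMode) else mode
    chrom_len = None
    base = track if mode == StrandMode.UNSTRANDED else plus_track
    if mode == StrandMode.STRANDED and (plus_track is None or minus_track is None):
        raise ConfigurationError("stranded mode needs plus_track and minus_track")
    chrom_len = len(base.counts[site.chrom]) * base.bin_width if site.chrom in base.counts else 0
    if site.summit < FLANK_BP or site.summit + FLANK_BP > chrom_len:
        raise SiteNearEdgeError(
            f"{site.site_id}: summit {site.chrom}:{site.summit} within {FLANK_BP} bp "
            "of a chromosome end"
        )
    if track.total_reads <= 0:
        raise ConfigurationError("cannot profile against an empty library")

    left_track = minus_track if mode == StrandMode.STRANDED else track
    right_track = plus_track if mode == StrandMode.STRANDED else track
    n_total = N_SIGNAL_BINS + N_BACKGROUND_BINS
    right = np.empty(n_total)
    left = np.empty(n_total)
    for i in range(1, n_total + 1):
        right[i - 1] = _bin_rpkm(
            right_track, site.chrom, site.summit + (i - 1) * BIN_BP, site.summit + i * BIN_BP
        )
        left[i - 1] = _bin_rpkm(
            left_track, site.chrom, site.summit - i * BIN_BP, site.summit - (i - 1) * BIN_BP
        )
    return (
        BinProfile(site.site_id, Side.LEFT, left[:N_SIGNAL_BINS], left[N_SIGNAL_BINS:]),
        BinProfile(site.site_id, Side.RIGHT, right[:N_SIGNAL_BINS], right[N_SIGNAL_BINS:]),
    )


def background_level(profile: BinProfile) -> float:
    """Per-side background: the maximum RPKM over the 2.5-5 kb bins."""
    return float(profile.background_bins.max()) if len(profile.background_bins) else 0.0


def max_resection_endpoint(
    signal_bins: np.ndarray | BinProfile,
    background: float,
    window_bins: int = WINDOW_BINS,
    bin_width: int = BIN_BP,
) -> int:
    """Maximum resection endpoint (bp from the summit) for one side.

    Windows of ``window_bins`` consecutive bins slide outward one bin at a
    time. The scan stops at the first window in which more than half of the
    bins have signal at or below ``background``; the endpoint is the outer
    edge of the last above-background bin inside that window. If that window
    holds no above-background bin, the last above-background bin before the
    window is used (0 when there is none). If no window ever satisfies the
    majority rule the endpoint is capped at the scan limit.
    """
    if isinstance(signal_bins, BinProfile):
        signal_bins = signal_bins.signal_bins
    bins = np.asarray(signal_bins, dtype=float)
    n = len(bins)
    if window_bins < 1 or window_bins > n:
        raise ConfigurationError("window_bins must be in [1, n_bins]")
    above = bins > background
    majority = window_bins // 2 + 1  # "more than half"
    for k in range(n - window_bins + 1):
        window = above[k : k + window_bins]
        if window_bins - int(window.sum()) >= majority:
            if window.any():
                j = k + int(np.flatnonzero(window)[-1])
                return (j + 1) * bin_width
            prev = np.flatnonzero(above[:k])
            return (int(prev[-1]) + 1) * bin_width if prev.size else 0
    return n * bin_width


def call_resection(
    track: CoverageTrack,
    site: BreakSite,
    mode: StrandMode | str = StrandMode.UNSTRANDED,
    plus_track: CoverageTrack | None = None,
    minus_track: CoverageTrack | None = None,
    window_bins: int = WINDOW_BINS,
) -> ResectionCall:
    """Per-side endpoints with per-side backgrounds for one break site."""
    left, right = bin_profile(track, site, mode, plus_track, minus_track)
    bg_left = background_level(left)
    bg_right = background_level(right)
    return ResectionCall(
        site_id=site.site_id,
        endpoint_left=max_resection_endpoint(left, bg_left, window_bins),
        endpoint_right=max_resection_endpoint(right, bg_right, window_bins),
        background_left=bg_left,
        background_right=bg_right,
    )


def call_resection_table(
    track: CoverageTrack,
    sites: Sequence[BreakSite],
    mode: StrandMode | str = StrandMode.UNSTRANDED,
    plus_track: CoverageTrack | None = None,
    minus_track: CoverageTrack | None = None,
    window_bins: int = WINDOW_BINS,
    resected_min_bp: int = RESECTED_MIN_BP,
) -> pd.DataFrame:
    """Resection calls for many sites; near-edge sites are skipped with a warning."""
    rows = []
    for site in sites:
        try:
            call = call_resection(track, site, mode, plus_track, minus_track, window_bins)
        except SiteNearEdgeError as exc:
            logger.warning("skipping site: %s", exc)
            continue
        rows.append(
            {
                "site_id": call.site_id,
                "endpoint_left": call.endpoint_left,
                "endpoint_right": call.endpoint_right,
                "max_endpoint": call.max_endpoint,
                "background_left": call.background_left,
                "background_right": call.background_right,
                "resected": call.max_endpoint > resected_min_bp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "endpoint_left",
            "endpoint_right",
            "max_endpoint",
            "background_left",
            "background_right",
            "resected",
        ],
    )


def stratify_by_resection(
    calls: pd.DataFrame, persistence: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Split per-site persistence by the resected flag.

    ``calls`` needs columns ``site_id, resected``; ``persistence`` needs
    ``site_id, persistence`` (one timepoint's records). Returns summary
    statistics per group; an empty group is reported with n = 0.
    """
    flags = dict(zip(calls["site_id"], calls["resected"]))
    groups: dict[str, list[float]] = {"resected": [], "non_resected": []}
    for row in persistence.itertuples(index=False):
        if row.site_id not in flags:
            continue
        key = "resected" if flags[row.site_id] else "non_resected"
        groups[key].append(float(row.persistence))
    out = {}
    for key, values in groups.items():
        arr = np.asarray(values, dtype=float)
        out[key] = {
            "n": int(arr.size),
            "median": float(np.median(arr)) if arr.size else float("nan"),
            "mean": float(arr.mean()) if arr.size else float("nan"),
        }
    return out
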