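"""Break persistence: per-site signal at a washout timepoint relative to the
pre-washout ("initial") signal of the same treatment arm, plus the coarser
fraction-of-initial-breaks metric based on detection alone.

Persistence is a plain ratio and is deliberately not clipped above 1: a site
gaining signal after washout is reported as such. Sites whose initial signal
is zero have no defined ratio and are excluded (counted and logged); sites
detected initially but absent from a later sample contribute a ratio of 0 so
that vanished breaks pull the distribution down rather than silently
disappearing. Because the ratio is formed within one site, any common scaling
of the two libraries (library depth, spike factor) cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedSignalError

logger = logging.getLogger(__name__)


@dataclass
class PersistenceRecord:
    site_id: str
    timepoint: str
    persistence: float
    detected_at_timepoint: bool | None = None

    def __post_init__(self) -> None:
        if self.persistence < 0:
            raise ValueError("persistence must be >= 0")


def persistence_ratio(signal_timepoint: float, signal_initial: float) -> float:
    """Signal at a washout timepoint over initial (pre-washout) signal."""
    if signal_initial <= 0:
        raise UndefinedSignalError("persistence undefined for zero initial signal")
    if signal_timepoint < 0:
        raise ValueError("signals must be >= 0")
    return signal_timepoint / signal_initial


def fraction_initial_breaks(
    detected_initial: Set[str], detected_timepoint: Set[str]
) -> float:
    """Percent of initially detected breaks still detected at a timepoint."""
    if not detected_initial:
        raise ConfigurationError("empty initial detection set")
    still = len(set(detected_timepoint) & set(detected_initial))
    return 100.0 * still / len(detected_initial)


def persistence_table(
    initial: Mapping[str, float],
    timepoints: Mapping[str, Mapping[str, float]],
    detected: Mapping[str, Set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site persistence for each timepoint plus a per-timepoint summary.

    ``initial`` maps site_id -> pre-washout signal; ``timepoints`` maps a
    timepoint label to its site -> signal mapping (missing sites count as 0).
    Returns (records, summary); the summary carries n, mean, median and
    quartiles of the finite ratios, and the count of excluded
    (zero-initial) sites.
    """
    records = []
    summaries = []
    for label, signals in timepoints.items():
        ratios = []
        n_excluded = 0
        for site_id, init in initial.items():
            if init <= 0:
                n_excluded += 1
                continue
            value = signals.get(site_id, 0.0)
            ratio = persistence_ratio(value, init)
            flag = None if detected is None else site_id in detected.get(label, set())
            records.append(
                {
                    "site_id": site_id,
                    "timepoint": label,
                    "persistence": ratio,
                    "detected_at_timepoint": flag,
                }
            )
            ratios.append(ratio)
        if n_excluded:
            logger.warning(
                "%s: excluded %d sites with zero initial signal", label, n_excluded
            )
        arr = np.asarray(ratios, dtype=float)
        summaries.append(
            {
                "timepoint": label,
                "n": arr.size,
                "n_excluded": n_excluded,
                "mean": float(arr.mean()) if arr.size else np.nan,
                "median": float(np.median(arr)) if arr.size else np.nan,
                "q1": float(np.percentile(arr, 25)) if arr.size else np.nan,
                "q3": float(np.percentile(arr, 75)) if arr.size else np.nan,
            }
        )
    rec_frame = pd.DataFrame(
        records, columns=["site_id", "timepoint", "persistence", "detected_at_timepoint"]
    )
    sum_frame = pd.DataFrame(
        summaries, columns=["timepoint", "n", "n_excluded", "mean", "median", "q1", "q3"]
    )
    return rec_frame, sum_frame
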