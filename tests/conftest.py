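"""Shared helpers for simulation-based tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import endseq as e

settings.register_profile("det", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("det")

SITE_FLANK = 2500  # summit-centered quantification window half-width (bp)


def make_meta(sample_id, nuclease, timepoint, treatment="ETO", spike=0.025):
    return e.SampleMeta(sample_id, treatment, nuclease, timepoint, spike)


def sites_from_truths(truths, flank=SITE_FLANK):
    return [
        e.BreakSite.from_summit(t.site_id, t.chrom, t.summit, flank) for t in truths
    ]


def simulate_track(truths, spikes, meta, cfg, bin_width=1):
    """Simulate one library and bin it at single-base resolution."""
    reads = e.simulate_sample(truths, spikes, meta, cfg)
    track = e.coverage_from_reads(reads, bin_width, cfg.chrom_sizes)
    return reads, track


def cell_percentages(track, sites, spikes, spike_fraction=0.025, window_bp=2000):
    """Per-site spike-normalized cell-percentage map for one sample."""
    stats = e.spike_in_factor(track, spikes, window_bp, spike_fraction)
    return (
        {s.site_id: e.to_cell_percentage(e.rpkm(track, s.interval), stats) for s in sites},
        stats,
    )


def spike_cv(stats: "e.SpikeInStats") -> float:
    """Coefficient of variation of the spike-in mean (normalization noise)."""
    per = np.asarray(stats.per_site_rpkm, dtype=float)
    if per.size < 2 or stats.mean_rpkm <= 0:
        return 0.0
    return float(per.std(ddof=1) / (stats.mean_rpkm * np.sqrt(per.size)))


@pytest.fixture
def tiny_genome():
    return {"chr1": 1_000_000}
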