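"""Sliding-window endpoint caller: hand-worked scans, brute-force oracle
agreement, invariances, and recovery on simulated resection tracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import endseq as e
from conftest import make_meta, sites_from_truths


def brute_force_endpoint(bins, background, window=10, bin_bp=50):
    """Independent re-statement of the scan rule by full enumeration."""
    above = [b > background for b in bins]
    n = len(bins)
    for k in range(n - window + 1):
        win = above[k : k + window]
        n_low = sum(1 for a in win if not a)
        if n_low >= window // 2 + 1:  # more than half at or below background
            inside = [k + i for i, a in enumerate(win) if a]
            if inside:
                return (max(inside) + 1) * bin_bp
            before = [i for i in range(k) if above[i]]
            return (max(before) + 1) * bin_bp if before else 0
    return n * bin_bp


class TestEndpointScan:
    def test_hand_worked_600bp_example(self):
        bins = np.array([5.0] * 12 + [0.5] * 38)
        assert e.max_resection_endpoint(bins, 1.0) == 600

    def test_all_below_background_is_zero(self):
        assert e.max_resection_endpoint(np.full(50, 0.5), 1.0) == 0

    def test_all_above_background_caps_at_scan_limit(self):
        assert e.max_resection_endpoint(np.full(50, 5.0), 1.0) == 2500

    def test_equal_to_background_counts_as_low(self):
        # the rule says "equal to or lower"; a bin at exactly background is low
        bins = np.full(50, 1.0)
        assert e.max_resection_endpoint(bins, 1.0) == 0

    def test_fallback_to_last_bin_before_window(self):
        # signal in bins 1-2 only: the first window holds bins 1-10 with two
        # above-background bins, so the endpoint lands on bin 2
        bins = np.zeros(50)
        bins[:2] = 5.0
        assert e.max_resection_endpoint(bins, 1.0) == 100

    def test_oracle_agreement_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            bins = rng.choice([0.0, 0.5, 1.0, 2.0, 5.0], size=50)
            bg = rng.choice([0.0, 0.5, 1.0])
            assert e.max_resection_endpoint(bins, bg) == brute_force_endpoint(bins, bg)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_uniform_scaling(self, c):
        rng = np.random.default_rng(7)
        bins = rng.gamma(1.0, 2.0, size=50)
        bg = 1.5
        assert e.max_resection_endpoint(bins * c, bg * c) == e.max_resection_endpoint(
            bins, bg
        )

    def test_raising_one_bin_never_decreases_endpoint(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            bins = rng.choice([0.0, 0.5, 2.0], size=50)
            base = e.max_resection_endpoint(bins, 1.0)
            j = rng.integers(0, 50)
            bumped = bins.copy()
            bumped[j] = bins[j] + 3.0
            assert e.max_resection_endpoint(bumped, 1.0) >= base

    def test_endpoint_bounds(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            bins = rng.gamma(0.3, 1.0, size=50)
            ep = e.max_resection_endpoint(bins, float(rng.uniform(0, 1)))
            assert 0 <= ep <= 2500


class TestBackground:
    def _profile(self, bg_bins):
        return e.BinProfile("s", e.Side.RIGHT, np.zeros(50), np.asarray(bg_bins))

    def test_zero_background(self):
        assert e.background_level(self._profile(np.zeros(50))) == 0.0

    def test_max_not_mean(self):
        bins = np.full(50, 0.1)
        bins[-1] = 0.9
        assert e.background_level(self._profile(bins)) == pytest.approx(0.9)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        bins = rng.random(50)
        assert e.background_level(self._profile(bins)) == e.background_level(
            self._profile(rng.permutation(bins))
        )


class TestBinProfile:
    def _track_with_reads(self, positions, strands=None, chrom_len=40_000):
        n = len(positions)
        strands = strands or ["+"] * n
        reads = e.ReadEndSet.from_arrays(["chr1"] * n, positions, strands)
        return e.coverage_from_reads(reads, 1, {"chr1": chrom_len})

    def test_read_right_of_summit_fills_right_bin_only(self):
        track = self._track_with_reads([10_120])
        site = e.BreakSite.from_summit("s", "chr1", 10_000, 2500)
        left, right = e.bin_profile(track, site)
        assert right.signal_bins[2] > 0  # bin 3 covers +100..+150
        assert right.signal_bins.sum() == right.signal_bins[2]
        assert left.signal_bins.sum() == 0

    def test_symmetric_reads_give_symmetric_profiles(self):
        track = self._track_with_reads([10_000 - 120, 10_000 + 120])
        site = e.BreakSite.from_summit("s", "chr1", 10_000, 2500)
        left, right = e.bin_profile(track, site)
        np.testing.assert_allclose(left.signal_bins, right.signal_bins)

    def test_profile_conserves_flank_reads(self):
        rng = np.random.default_rng(5)
        offsets = rng.integers(0, 5_000, size=200)
        track = self._track_with_reads(list(10_000 + offsets))
        site = e.BreakSite.from_summit("s", "chr1", 10_000, 2500)
        _, right = e.bin_profile(track, site)
        # RPKM -> count conversion: bin count = rpkm * (0.05 kb) * (total/1e6)
        factor = 0.05 * track.total_reads / 1e6
        total = (right.signal_bins.sum() + right.background_bins.sum()) * factor
        assert total == pytest.approx(len(offsets))

    def test_summit_near_edge_raises(self):
        track = self._track_with_reads([3_000])
        site = e.BreakSite.from_summit("s", "chr1", 3_000, 1000)
        with pytest.raises(e.SiteNearEdgeError):
            e.bin_profile(track, site)

    def test_stranded_mode_splits_by_side(self):
        positions = [10_000 - 130, 10_000 + 220]
        strands = ["-", "+"]
        reads = e.ReadEndSet.from_arrays(["chr1"] * 2, positions, strands)
        full = e.coverage_from_reads(reads, 1, {"chr1": 40_000})
        plus = e.coverage_from_reads(reads, 1, {"chr1": 40_000}, strand="+", total_reads=2)
        minus = e.coverage_from_reads(reads, 1, {"chr1": 40_000}, strand="-", total_reads=2)
        site = e.BreakSite.from_summit("s", "chr1", 10_000, 2500)
        call = e.call_resection(full, site, "STRANDED", plus_track=plus, minus_track=minus)
        assert call.endpoint_left == 150  # minus-strand read in left bin 3
        assert call.endpoint_right == 250  # plus-strand read in right bin 5
        assert call.resected


class TestCalls:
    def test_max_endpoint_and_threshold(self):
        call = e.ResectionCall("s", 600, 50, 0.0, 0.0)
        assert call.max_endpoint == 600 and call.resected
        boundary = e.ResectionCall("s", 100, 100, 0.0, 0.0)
        assert not boundary.resected  # strict > 100

    def test_deterministic_fixed_length_recovery(self):
        cfg = e.SimConfig(
            chrom_sizes={"chr1": 600_000},
            n_sites=10,
            n_spike_sites=0,
            cells_per_sample=800,
            background_rate=0.0,
            p_cleaved=1.0,
            f_reversible=0.0,
            f_irreversible=0.0,
            f_free=1.0,
            resection_mean_bp=400.0,
            resection_max_bp=400.0,
            summit_jitter_bp=0,
            seed=21,
        )
        truths, _ = e.simulate_genome(cfg)
        meta = make_meta("w0", e.Nuclease.EXOVII_EXOT, e.Timepoint.WASHOUT_0H)
        reads = e.simulate_sample(truths, [], meta, cfg)
        track = e.coverage_from_reads(reads, 1, cfg.chrom_sizes)
        calls = e.call_resection_table(track, sites_from_truths(truths))
        assert (np.abs(calls["max_endpoint"] - 400) <= 50).all()

    def test_stratification_groups(self):
        import pandas as pd

        calls = pd.DataFrame(
            {"site_id": ["a", "b", "c"], "resected": [True, True, False]}
        )
        pers = pd.DataFrame(
            {"site_id": ["a", "b", "c"], "persistence": [0.5, 0.7, 0.1]}
        )
        out = e.stratify_by_resection(calls, pers)
        assert out["resected"]["n"] == 2
        assert out["resected"]["median"] == pytest.approx(0.6)
        assert out["non_resected"]["n"] == 1

    def test_all_resected_leaves_other_group_empty(self):
        import pandas as pd

        calls = pd.DataFrame({"site_id": ["a"], "resected": [True]})
        pers = pd.DataFrame({"site_id": ["a"], "persistence": [0.4]})
        out = e.stratify_by_resection(calls, pers)
        assert out["non_resected"]["n"] == 0
        assert np.isnan(out["non_resected"]["median"])
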