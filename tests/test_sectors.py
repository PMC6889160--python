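"""Unique-cluster detection, sector assignment, permutation FPR."""

import math

import numpy as np
import pytest

from methsector.clustering import ClusterConfig, PatternCluster
from methsector.ingest import Window
from methsector.matrix import DepthGate
from methsector.sectors import (
    SectorConfig,
    assign_sectors,
    find_unique_clusters,
    permutation_fpr,
    run_sector_scan,
)
from methsector.simulate import planted_mixture, simulate_reads


def cluster(window, n_meth, n_total, count_a, count_b):
    pattern = tuple([1] * n_meth + [0] * (n_total - n_meth))
    return PatternCluster(window, pattern, count_a + count_b, count_a, count_b)


@pytest.fixture
def w20():
    return Window("chr1", 0, 100, tuple(range(2, 42, 2)))


class TestFindUniqueClusters:
    def test_zero_contamination_rule(self, w20):
        ua, ub, shared = find_unique_clusters(
            [
                cluster(w20, 20, 20, 6, 0),
                cluster(w20, 0, 20, 0, 5),
                cluster(w20, 10, 20, 5, 1),
            ]
        )
        assert [c.count_a for c in ua] == [6]
        assert [c.count_b for c in ub] == [5]
        assert len(shared) == 1

    def test_empty_input(self):
        assert find_unique_clusters([]) == ([], [], [])

    def test_contamination_tolerance_relaxes_uniqueness(self, w20):
        c = cluster(w20, 20, 20, 19, 1)
        assert find_unique_clusters([c])[0] == []
        ua, _, _ = find_unique_clusters([c], contamination_tolerance=0.1)
        assert ua == [c]


class TestAssignSectors:
    def test_control_high_knockout_low_is_sector_2(self, w20):
        a = assign_sectors([cluster(w20, 16, 20, 5, 0)], [cluster(w20, 4, 20, 0, 5)])
        assert a.sectors == {2}

    def test_converse_is_sector_4(self, w20):
        a = assign_sectors([cluster(w20, 4, 20, 5, 0)], [cluster(w20, 16, 20, 0, 5)])
        assert a.sectors == {4}

    def test_both_high_sector_1_and_both_low_sector_3(self, w20):
        a1 = assign_sectors([cluster(w20, 18, 20, 5, 0)], [cluster(w20, 16, 20, 0, 5)])
        assert a1.sectors == {1}
        a3 = assign_sectors([cluster(w20, 2, 20, 5, 0)], [cluster(w20, 4, 20, 0, 5)])
        assert a3.sectors == {3}

    def test_dead_band_disqualifies(self, w20):
        # A-unique level 0.50 sits strictly between 0.45 and 0.55
        a = assign_sectors([cluster(w20, 10, 20, 5, 0)], [cluster(w20, 6, 20, 0, 5)])
        assert a is not None and a.sectors == frozenset()

    def test_thresholds_inclusive_at_boundaries(self, w20):
        # levels exactly 0.55 and 0.45 qualify
        a = assign_sectors([cluster(w20, 11, 20, 5, 0)], [cluster(w20, 9, 20, 0, 5)])
        assert 2 in a.sectors

    def test_just_inside_dead_band_does_not_qualify(self, w20):
        # 0.50 on either axis cannot reach any sector
        a = assign_sectors([cluster(w20, 10, 20, 5, 0)], [cluster(w20, 10, 20, 0, 5)])
        assert a.sectors == frozenset()

    def test_one_sided_window_not_assignable(self, w20):
        assert assign_sectors([cluster(w20, 16, 20, 5, 0)], []) is None
        assert assign_sectors([], [cluster(w20, 4, 20, 0, 5)]) is None

    def test_any_pair_rule_allows_dual_sector(self, w20):
        ua = [cluster(w20, 20, 20, 5, 0), cluster(w20, 2, 20, 4, 0)]
        ub = [cluster(w20, 0, 20, 0, 5), cluster(w20, 18, 20, 0, 4)]
        a = assign_sectors(ua, ub)
        assert a.sectors == {1, 2, 3, 4}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SectorConfig(high_threshold=0.45, low_threshold=0.55)


class TestSectorScan:
    def test_identical_pattern_sets_give_no_unique_clusters(self):
        """With both conditions sampling the same two abundant patterns and
        no noise, no cluster can be condition-unique."""
        from conftest import fragment

        w = Window("chr1", 0, 100, (10, 50, 90))
        frags_a, frags_b = [], []
        for i in range(15):
            frags_a.append(fragment(f"a{i}", "A", "chr1", {10: 1, 50: 1, 90: 1}))
            frags_b.append(fragment(f"b{i}", "B", "chr1", {10: 1, 50: 1, 90: 1}))
            frags_a.append(fragment(f"a{i}x", "A", "chr1", {10: 0, 50: 0, 90: 0}))
            frags_b.append(fragment(f"b{i}x", "B", "chr1", {10: 0, 50: 0, 90: 0}))
        scan = run_sector_scan(frags_a, frags_b, [w])
        assert scan.n_gated == 1
        assert scan.sector_counts == {1: 0, 2: 0, 3: 0, 4: 0}

    def test_planted_window_called_sector_2(self):
        spec = planted_mixture(n_planted=1, n_null=2, error_rate=0.0, seed=4)
        fa, fb, truth = simulate_reads(spec, seed=4)
        scan = run_sector_scan(fa, fb, spec.windows)
        (called,) = scan.sector_windows(2)
        assert called.window.start == int(truth[truth.planted].start.iloc[0])

    def test_label_swap_exchanges_sectors_exactly(self):
        spec = planted_mixture(n_planted=10, n_null=10, seed=8)
        fa, fb, _ = simulate_reads(spec, seed=8)
        fwd = run_sector_scan(fa, fb, spec.windows)
        rev = run_sector_scan(fb, fa, spec.windows)
        key = lambda scan, s: {r.window.start for r in scan.sector_windows(s)}
        assert key(fwd, 2) == key(rev, 4)
        assert key(fwd, 4) == key(rev, 2)
        assert key(fwd, 1) == key(rev, 1)
        assert key(fwd, 3) == key(rev, 3)

    def test_raising_filters_never_adds_windows(self):
        spec = planted_mixture(n_planted=15, n_null=15, coverage=20, seed=12)
        fa, fb, _ = simulate_reads(spec, seed=12)
        base = run_sector_scan(
            fa, fb, spec.windows, depth_gate=DepthGate(10), cluster_config=ClusterConfig(4)
        )
        stricter_gate = run_sector_scan(
            fa, fb, spec.windows, depth_gate=DepthGate(15), cluster_config=ClusterConfig(4)
        )
        stricter_cluster = run_sector_scan(
            fa, fb, spec.windows, depth_gate=DepthGate(10), cluster_config=ClusterConfig(6)
        )
        n_assigned = lambda scan: sum(
            1 for r in scan.assignable if r.assignment.sectors
        )
        assert n_assigned(stricter_gate) <= n_assigned(base)
        assert n_assigned(stricter_cluster) <= n_assigned(base)

    def test_master_table_has_one_row_per_gated_window(self):
        spec = planted_mixture(n_planted=3, n_null=3, seed=2)
        fa, fb, _ = simulate_reads(spec, seed=2)
        scan = run_sector_scan(fa, fb, spec.windows)
        df = scan.to_frame()
        assert len(df) == scan.n_gated
        assert set(df.columns) >= {"chrom", "start", "end", "sectors"}


class TestPermutationFpr:
    def test_zero_observed_reports_nan(self):
        spec = planted_mixture(n_planted=2, n_null=2, seed=3)
        fa, fb, _ = simulate_reads(spec, seed=3)
        scan = run_sector_scan(fa, fb, spec.windows)
        results = permutation_fpr(scan)
        assert scan.sector_counts[3] == 0
        assert math.isnan(results[3].fpr)

    def test_fixed_seed_is_bit_reproducible(self):
        spec = planted_mixture(n_planted=5, n_null=5, seed=6)
        fa, fb, _ = simulate_reads(spec, seed=6)
        scan = run_sector_scan(fa, fb, spec.windows)
        cfg = SectorConfig(rng_seed=123)
        r1 = permutation_fpr(scan, sector_config=cfg)
        r2 = permutation_fpr(scan, sector_config=cfg)
        assert {s: r.permuted_counts for s, r in r1.items()} == {
            s: r.permuted_counts for s, r in r2.items()
        }

    def test_different_seeds_vary_permuted_counts(self):
        from methsector.simulate import make_null_pair, null_mixture

        spec = null_mixture(n_windows=120, seed=5)
        fa, fb, _ = make_null_pair(spec, seed=5)
        scan = run_sector_scan(fa, fb, spec.windows)
        r1 = permutation_fpr(scan, sector_config=SectorConfig(rng_seed=1))
        r2 = permutation_fpr(scan, sector_config=SectorConfig(rng_seed=2))
        # counts may coincide sector-by-sector but not across all iterations
        assert any(r1[s].permuted_counts != r2[s].permuted_counts for s in r1)

    def test_strong_planted_effect_gives_small_fpr(self):
        spec = planted_mixture(n_planted=50, n_null=20, seed=9)
        fa, fb, _ = simulate_reads(spec, seed=9)
        scan = run_sector_scan(fa, fb, spec.windows)
        results = permutation_fpr(scan)
        assert results[2].observed_count >= 45
        assert results[2].fpr < 0.2
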